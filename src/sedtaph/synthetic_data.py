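"""Synthetic sedaDNA landscapes and alignments with known ground truth.

The landscape generator emulates the statistical structure the pipeline
assumes in real core data:

* taxa fall into disjoint guild blocks; each block has a Dirichlet
  composition archetype over its taxa;
* each core carries a temporally autocorrelated latent walk of local guild
  weights (soft-max of a Gaussian random walk), so taxa of one block
  co-occur across samples;
* each sediment class has a distal influx environment — its own guild-weight
  walk around a class-specific archetype, drifting at a configurable
  multiple of the local rate — and the observed composition of a sample is
  cl * local + (1 - cl) * influx with cl set by its sediment class;
* optional diffusion mixes each sample with the one below it with weight
  exp(-lambda * x);
* read counts are multinomial at the configured sequencing depth, ages are
  linear in depth, and everything is reproducible from one seed.

The alignment generator plants a chosen number of exclusively shared SNPs
between an ancient row and each reference taxon, concatenates read blocks
with 5-base gap separators, and can add deamination-like C->T flips at read
ends that the clip filter is designed to remove.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cladesnp import BLOCK_SEPARATOR_LEN, ConcatAlignment
from .profiles_io import SampleMetadata, TaxonCountTable

_DEFAULT_CL = {
    "clay": 0.95, "silt": 0.95, "fine_sand": 0.7,
    "medium_sand": 0.55, "coarse_sand": 0.4, "other": 0.7,
}


@dataclass
class SimConfig:
    """Study-scale defaults: 4 guild blocks of 10 taxa, 6 cores x 10 samples,
    5,000 reads per sample, fine sediment above coarse in each core."""

    n_cores: int = 6
    samples_per_core: int = 10
    n_taxa: int = 40
    n_guilds: int = 4
    depth_per_sample: int = 5000
    cl_by_sediment: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_CL))
    lambda_diffusion: float = 0.0          # 1/cm; 0 disables diffusion
    drift_rate: float = 1.5                # sd of the latent guild-weight walk step
    archetype_concentration: float = 3.0   # Dirichlet alpha of within-guild compositions
    influx_drift_mult: float = 0.3         # distal drift rate relative to local
    influx_mode: str = "distal"            # 'distal' | 'lagged'
    influx_lag: int = 3                    # steps, for influx_mode='lagged'
    sediment_sequence: list[str] | None = None  # per-sample classes, top to bottom
    sample_spacing_cm: float = 10.0
    age_at_surface: float = 8000.0         # cal BP at depth 0
    age_per_cm: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for sed, cl in self.cl_by_sediment.items():
            if not 0.0 <= cl <= 1.0:
                raise ValueError(f"cl for {sed} outside [0, 1]")
        if self.n_guilds > self.n_taxa:
            raise ValueError("need at least one taxon per guild")
        if self.influx_mode not in {"distal", "lagged"}:
            raise ValueError("influx_mode must be 'distal' or 'lagged'")

    def sediments(self) -> list[str]:
        if self.sediment_sequence is not None:
            if len(self.sediment_sequence) != self.samples_per_core:
                raise ValueError("sediment_sequence length != samples_per_core")
            return list(self.sediment_sequence)
        half = self.samples_per_core // 2
        return ["silt"] * half + ["coarse_sand"] * (self.samples_per_core - half)


@dataclass
class GroundTruth:
    guild_of_taxon: dict[str, int]
    local_composition: dict[str, np.ndarray]    # sample_id -> taxon probs
    influx_composition: dict[str, np.ndarray]
    observed_composition: dict[str, np.ndarray]  # after mixing + diffusion
    realized_cl: dict[str, float]
    realized_lambda: float


def _softmax(z: np.ndarray) -> np.ndarray:
    e = np.exp(z - z.max())
    return e / e.sum()


def simulate_landscape(
    cfg: SimConfig,
) -> tuple[TaxonCountTable, list[SampleMetadata], GroundTruth]:
    """Simulate a multi-core landscape; see the module docstring for the model."""
    root = np.random.SeedSequence(cfg.seed)
    # independent sub-streams so per-core output is stable under reordering
    ss_global, ss_influx, *ss_cores = root.spawn(2 + cfg.n_cores)
    rng = np.random.default_rng(ss_global)

    taxa = [f"taxon_{i:03d}" for i in range(cfg.n_taxa)]
    blocks = np.array_split(np.arange(cfg.n_taxa), cfg.n_guilds)
    guild_of_taxon = {taxa[i]: g for g, idx in enumerate(blocks) for i in idx}
    # within-guild composition archetypes on disjoint taxon supports
    archetypes = np.zeros((cfg.n_guilds, cfg.n_taxa))
    for g, idx in enumerate(blocks):
        archetypes[g, idx] = rng.dirichlet(
            np.full(len(idx), cfg.archetype_concentration))

    sediments = cfg.sediments()
    classes = sorted(set(sediments))
    # distal influx environments: one guild-weight walk per sediment class
    rng_influx = np.random.default_rng(ss_influx)
    influx_base = {c: rng_influx.normal(0.0, 1.5, size=cfg.n_guilds) for c in classes}
    influx_walk: dict[str, list[np.ndarray]] = {}
    for c in classes:
        z = influx_base[c].copy()
        walk = []
        for _ in range(cfg.samples_per_core):
            walk.append(_softmax(z))
            z = z + rng_influx.normal(
                0.0, cfg.drift_rate * cfg.influx_drift_mult, size=cfg.n_guilds)
        influx_walk[c] = walk

    counts = {}
    metadata: list[SampleMetadata] = []
    local_comp: dict[str, np.ndarray] = {}
    influx_comp: dict[str, np.ndarray] = {}
    observed: dict[str, np.ndarray] = {}
    realized_cl: dict[str, float] = {}

    for ci, ss_core in enumerate(ss_cores):
        core_id = f"C{ci + 1:02d}"
        rng_c = np.random.default_rng(ss_core)
        z = rng_c.normal(0.0, 1.5, size=cfg.n_guilds)
        local_hist: list[np.ndarray] = []
        mixed: list[np.ndarray] = []
        sample_ids: list[str] = []
        for si in range(cfg.samples_per_core):
            w_local = _softmax(z)
            p_local = w_local @ archetypes
            local_hist.append(p_local)
            sed = sediments[si]
            cl = cfg.cl_by_sediment.get(sed, 0.7)
            if cfg.influx_mode == "distal":
                w_inf = influx_walk[sed][si]
                p_inf = w_inf @ archetypes
            else:  # lagged copy of the local environment
                lagged = local_hist[max(0, si - cfg.influx_lag)]
                p_inf = lagged
            p_obs = cl * p_local + (1.0 - cl) * p_inf
            sid = f"{core_id}-{si + 1:02d}"
            sample_ids.append(sid)
            local_comp[sid] = p_local
            influx_comp[sid] = p_inf
            observed[sid] = p_obs
            realized_cl[sid] = cl
            mixed.append(p_obs)
            z = z + rng_c.normal(0.0, cfg.drift_rate, size=cfg.n_guilds)

        # diffusion: mix each sample towards the one below (pre-mix donor)
        if cfg.lambda_diffusion > 0:
            m = float(np.exp(-cfg.lambda_diffusion * cfg.sample_spacing_cm))
            pre = [p.copy() for p in mixed]
            for si in range(cfg.samples_per_core - 1):
                mixed[si] = (1.0 - m) * pre[si] + m * pre[si + 1]
                observed[sample_ids[si]] = mixed[si]

        for si, sid in enumerate(sample_ids):
            counts[sid] = rng_c.multinomial(cfg.depth_per_sample, mixed[si])
            depth = (si + 1) * cfg.sample_spacing_cm
            metadata.append(SampleMetadata(
                sample_id=sid, core_id=core_id, depth_cm=depth,
                sediment_class=sediments[si],
                laminated=sediments[si] in {"clay", "silt"},
                age_calBP=cfg.age_at_surface + cfg.age_per_cm * depth,
                age_sd=50.0, security="unknown", domain="unknown",
            ))

    table = TaxonCountTable(
        pd.DataFrame.from_dict(counts, orient="index", columns=taxa),
        drop_empty_taxa=False,
    )
    truth = GroundTruth(
        guild_of_taxon=guild_of_taxon,
        local_composition=local_comp,
        influx_composition=influx_comp,
        observed_composition=observed,
        realized_cl=realized_cl,
        realized_lambda=cfg.lambda_diffusion,
    )
    return table, metadata, truth


# -- alignment simulation --------------------------------------------------

BASES = np.array(list("ACGT"))
_TRANSVERSION_OF = {"A": "C", "C": "A", "G": "T", "T": "G"}


def simulate_alignment(
    n_taxa: int,
    n_reads: int,
    read_len: int,
    planted_shares: dict[str, int],
    seed: int,
    deamination_rate: float = 0.0,
) -> tuple[ConcatAlignment, dict[str, int]]:
    """Alignment of ``n_taxa`` references plus one ancient row.

    ``planted_shares`` maps reference taxon names (``ref_01`` ...) to the
    number of SNP columns exclusively shared between that taxon and the
    ancient row; planted states differ from the background by a transversion
    so the damage filters keep them.  ``deamination_rate`` flips ancient C->T
    (G->A) within the terminal 5 bases of each read block, emulating end
    damage that clipping removes.  Returns the alignment and a copy of the
    planted truth.
    """
    rng = np.random.default_rng(seed)
    names = [f"ref_{i + 1:02d}" for i in range(n_taxa)]
    unknown = set(planted_shares) - set(names)
    if unknown:
        raise ValueError(f"planted taxa not in alignment: {sorted(unknown)}")
    total_cols = n_reads * read_len
    interior = [
        c for c in range(total_cols)
        if (c % read_len) >= 5 and (c % read_len) < read_len - 5
    ]
    need = sum(planted_shares.values())
    if need > len(interior):
        raise ValueError("more planted SNPs than interior alignment columns")

    base = BASES[rng.integers(0, 4, size=total_cols)]
    rows = {n: base.copy() for n in names}
    ancient = base.copy()

    chosen = rng.choice(len(interior), size=need, replace=False)
    cols = iter([interior[i] for i in sorted(chosen)])
    for taxon, k in sorted(planted_shares.items()):
        for _ in range(k):
            c = next(cols)
            derived = _TRANSVERSION_OF[str(base[c])]
            rows[taxon][c] = derived
            ancient[c] = derived

    if deamination_rate > 0:
        for r in range(n_reads):
            start = r * read_len
            ends = list(range(start, start + 5)) + \
                list(range(start + read_len - 5, start + read_len))
            for c in ends:
                if rng.random() < deamination_rate:
                    if ancient[c] == "C":
                        ancient[c] = "T"
                    elif ancient[c] == "G":
                        ancient[c] = "A"

    sep = "-" * BLOCK_SEPARATOR_LEN

    def concat(arr: np.ndarray) -> str:
        parts = ["".join(arr[r * read_len:(r + 1) * read_len]) for r in range(n_reads)]
        return sep.join(parts)

    all_names = names + ["ancient"]
    seqs = [concat(rows[n]) for n in names] + [concat(ancient)]
    aln = ConcatAlignment(all_names, seqs, ancient="ancient")
    return aln, dict(planted_shares)
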