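"""Plant-guild construction from taxon co-occurrence, and guild profiles.

A plant guild is a group of taxa whose per-sample read frequencies co-vary
across sediment samples.  The pipeline is:

1. Pearson correlation (pmcc) between every taxon pair's frequency vectors.
2. Affine map of pmcc in [-1, 1] to a distance d = 1 - (pmcc + 1)/2 in [0, 1].
3. Classical (Torgerson) metric multidimensional scaling of the distance
   matrix into 10 dimensions.
4. Hypercube clustering: each axis is cut into three equal sections; taxa
   sharing a cell over the first k axes form a group, with k incremented per
   group until the split stabilises.
5. Guild validation: permutation p-values for pairwise association, a
   simple/complex type call (complex guilds hang off an anchor taxon), and a
   binomial enrichment tail probability against the false-discovery rate.
6. Per-sample guild profiles (read proportion per guild) and the Euclidean
   profile distance ∂ used by the taphonomy model.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .profiles_io import TaxonCountTable

logger = logging.getLogger("sedtaph")

UNASSIGNED = "unassigned"


@dataclass
class CorrelationMatrix:
    """Pairwise pmcc between taxon frequency vectors.

    ``dropped`` lists zero-variance taxa whose correlations are undefined;
    they are excluded from ``taxa``/``values`` and from clustering.
    """

    taxa: list[str]
    values: np.ndarray
    dropped: list[str] = field(default_factory=list)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.taxa, columns=self.taxa)


@dataclass
class GuildDistanceMatrix:
    taxa: list[str]
    values: np.ndarray


@dataclass
class Embedding:
    """Metric-scaling coordinates, dimensions ordered by decreasing eigenvalue."""

    taxa: list[str]
    coordinates: np.ndarray  # (n_taxa, dims)
    eigenvalues: np.ndarray  # (dims,)


@dataclass
class Guild:
    id: int
    members: frozenset[str]
    guild_type: str = "simple"  # 'simple' | 'complex'
    anchor: str | None = None

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ValueError("a guild needs at least 2 members")
        if self.guild_type == "simple" and self.anchor is not None:
            raise ValueError("simple guilds have no anchor")


@dataclass
class GuildProfile:
    """Per-sample read proportions over guilds plus an unassigned remainder."""

    sample_id: str
    proportions: dict[int, float]
    unassigned: float


# -- correlation and distance ---------------------------------------------

def pairwise_pmcc(table: TaxonCountTable) -> CorrelationMatrix:
    """Pearson correlation of per-sample frequency vectors for all taxon pairs.

    Frequencies (count / sample total), not raw counts, are correlated.
    Taxa constant across samples have undefined correlations and are dropped
    with a log message.
    """
    if len(table.samples) < 3:
        raise ValueError("need at least 3 samples for pairwise correlation")
    freq = table.frequencies()
    sd = freq.to_numpy().std(axis=0)
    keep_mask = sd > 1e-12  # tolerance absorbs float residue of constant columns
    dropped = [t for t, k in zip(table.taxa, keep_mask) if not k]
    if dropped:
        logger.info("excluding %d zero-variance taxa from correlation", len(dropped))
    kept = [t for t, k in zip(table.taxa, keep_mask) if k]
    x = freq.to_numpy()[:, keep_mask]
    corr = np.corrcoef(x, rowvar=False)
    corr = np.clip(corr, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    return CorrelationMatrix(taxa=kept, values=corr, dropped=dropped)


def corr_to_distance(c: CorrelationMatrix) -> GuildDistanceMatrix:
    """Map pmcc in [-1, 1] to a dissimilarity d = 1 - (pmcc + 1)/2 in [0, 1]."""
    d = 1.0 - (c.values + 1.0) / 2.0
    np.fill_diagonal(d, 0.0)
    return GuildDistanceMatrix(taxa=list(c.taxa), values=d)


# -- ordination ------------------------------------------------------------

def embed_mds(d: GuildDistanceMatrix, dims: int = 10) -> Embedding:
    """Classical (Torgerson) metric scaling of a distance matrix.

    Double-centres the squared distances, eigendecomposes, and scales the
    top eigenvectors by the square root of their eigenvalues.  Negative
    eigenvalues (non-Euclidean input) are truncated to zero with a warning.
    Each axis's sign is fixed so its largest-magnitude loading is positive,
    making the output deterministic.
    """
    n = len(d.taxa)
    if n < 3:
        raise ValueError("need at least 3 taxa to embed")
    if dims > n - 1:
        raise ValueError("dims must be <= number of taxa - 1")
    dm = np.asarray(d.values, dtype=float)
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (dm ** 2) @ j
    evals, evecs = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(evals)[::-1][:dims]
    evals, evecs = evals[order], evecs[:, order]
    if (evals < -1e-8 * max(1.0, float(np.abs(evals).max()))).any():
        logger.warning("distance matrix is not Euclidean; truncating negative eigenvalues")
    evals = np.clip(evals, 0.0, None)
    coords = evecs * np.sqrt(evals)
    # deterministic axis orientation: largest |loading| made positive
    for k in range(coords.shape[1]):
        col = coords[:, k]
        if col.any() and col[np.argmax(np.abs(col))] < 0:
            coords[:, k] = -col
    return Embedding(taxa=list(d.taxa), coordinates=coords, eigenvalues=evals)


# -- hypercube clustering --------------------------------------------------

def _section_indices(
    coords: np.ndarray, sections: int, scale: str = "shared"
) -> np.ndarray:
    """Per-dimension section index for each taxon.

    Each axis is cut into ``sections`` equal-width intervals, half-open and
    closed at the top, so boundary points fall in the lower section.  With
    ``scale='shared'`` (default) the section width is common to all axes —
    a third of the widest axis's range, with intervals centred on each
    axis's midpoint — as when every axis of an ordination is drawn at the
    same scale; low-eigenvalue axes whose spread fits inside one section
    then never split a group.  ``scale='axis'`` instead stretches each
    axis's own observed [min, max] over the ``sections`` intervals, which
    makes near-degenerate noise axes as divisive as informative ones.
    """
    lo = coords.min(axis=0)
    hi = coords.max(axis=0)
    if scale == "shared":
        width = np.full(coords.shape[1], (hi - lo).max() / sections)
        lo = (lo + hi) / 2.0 - width * sections / 2.0
    elif scale == "axis":
        width = (hi - lo) / sections
    else:
        raise ValueError("scale must be 'shared' or 'axis'")
    idx = np.zeros(coords.shape, dtype=int)
    ok = width > 0
    scaled = np.zeros_like(coords)
    scaled[:, ok] = (coords[:, ok] - lo[ok]) / width[ok]
    idx[:, ok] = np.ceil(scaled[:, ok]).astype(int) - 1
    return np.clip(idx, 0, sections - 1)


def hypercube_cluster(
    e: Embedding,
    start_dims: int = 3,
    sections: int = 3,
    stability: float = 0.9,
    section_scale: str = "shared",
) -> tuple[list[Guild], list[str]]:
    """Group taxa by shared hypercube cells, refining dimensions until stable.

    Taxa are first grouped by their joint section membership over the first
    ``start_dims`` axes.  Each group is then probed with one more axis at a
    time: if the extra axis produces no second subgroup of size >= 2, or the
    largest subgroup retains at least ``stability`` of the members, the group
    is declared stable and kept whole; otherwise it splits into the subgroups,
    each refined recursively.  Final singletons are reported as unassigned.

    Returns ``(guilds, unassigned_taxa)``.
    """
    dims = e.coordinates.shape[1]
    if dims < start_dims:
        raise ValueError("embedding has fewer dimensions than start_dims")
    sec = _section_indices(e.coordinates, sections, scale=section_scale)
    taxa = np.asarray(e.taxa, dtype=object)

    def cells(members: np.ndarray, upto: int) -> dict[tuple, np.ndarray]:
        keys = [tuple(sec[i, :upto]) for i in members]
        out: dict[tuple, list[int]] = {}
        for i, k in zip(members, keys):
            out.setdefault(k, []).append(i)
        return {k: np.asarray(v) for k, v in out.items()}

    def refine(members: np.ndarray, k: int) -> list[np.ndarray]:
        if len(members) < 2 or k >= dims:
            return [members]
        sub = list(cells(members, k + 1).values())
        if len(sub) == 1:
            return [members]  # extra axis does not split: stable
        sizes = sorted((len(s) for s in sub), reverse=True)
        stable = sizes[1] < 2 or sizes[0] >= stability * len(members)
        if stable:
            return [members]
        return [g for s in sub for g in refine(s, k + 1)]

    groups: list[np.ndarray] = []
    for members in cells(np.arange(len(taxa)), start_dims).values():
        groups.extend(refine(members, start_dims))

    guilds: list[Guild] = []
    unassigned: list[str] = []
    gid = 1
    for g in groups:
        names = sorted(taxa[g])
        if len(names) < 2:
            unassigned.extend(names)
            continue
        guilds.append(Guild(id=gid, members=frozenset(names)))
        gid += 1
    assigned = [t for g in guilds for t in g.members]
    assert len(assigned) == len(set(assigned)), "taxon assigned to two guilds"
    return guilds, sorted(unassigned)


# -- guild validation ------------------------------------------------------

def pair_association_pvalues(
    table: TaxonCountTable,
    n_perm: int = 999,
    seed: int | None = None,
) -> dict[tuple[str, str], float]:
    """One-sided permutation p-values for positive pairwise association.

    The observed statistic is the pmcc of the two taxa's frequency vectors;
    the null permutes sample labels independently per taxon.  p = (1 + number
    of permuted pmcc >= observed) / (1 + n_perm).  Pairs involving a constant
    taxon get p = 1.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    rng = np.random.default_rng(seed)
    freq = table.frequencies().to_numpy()
    n, t = freq.shape
    mean = freq.mean(axis=0)
    sd = freq.std(axis=0)
    constant = sd <= 1e-12
    z = np.zeros_like(freq)
    np.divide(freq - mean, sd, out=z, where=~constant)
    obs = (z.T @ z) / n
    exceed = np.zeros((t, t), dtype=np.int64)
    for _ in range(n_perm):
        zp = np.empty_like(z)
        for j in range(t):
            zp[:, j] = z[rng.permutation(n), j]
        exceed += (zp.T @ zp) / n >= obs - 1e-12
    pmat = (1.0 + exceed) / (1.0 + n_perm)
    out: dict[tuple[str, str], float] = {}
    taxa = table.taxa
    for i, j in itertools.combinations(range(t), 2):
        p = 1.0 if (constant[i] or constant[j]) else float(pmat[i, j])
        out[_pair_key(taxa[i], taxa[j])] = p
    return out


def _pair_key(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


def classify_guild_type(
    g: Guild,
    pair_pvalues: dict[tuple[str, str], float],
    alpha: float = 0.05,
) -> Guild:
    """Call a guild simple or complex from its pairwise association p-values.

    Simple: every member pair is significantly associated (p < alpha).
    Complex: otherwise; the anchor is the member with the most significant
    pairings (ties broken lexicographically).
    """
    members = sorted(g.members)
    sig_count = {m: 0 for m in members}
    all_sig = True
    for a, b in itertools.combinations(members, 2):
        key = _pair_key(a, b)
        if key not in pair_pvalues:
            raise KeyError(f"missing p-value for pair {key}")
        if pair_pvalues[key] < alpha:
            sig_count[a] += 1
            sig_count[b] += 1
        else:
            all_sig = False
    if all_sig:
        return Guild(id=g.id, members=g.members, guild_type="simple", anchor=None)
    anchor = min(members, key=lambda m: (-sig_count[m], m))
    return Guild(id=g.id, members=g.members, guild_type="complex", anchor=anchor)


def guild_enrichment(m: int, x: int, p0: float) -> float:
    """Upper-tail binomial probability P(X >= x), X ~ Bin(m, p0).

    Used to test whether the number of significant pairwise associations in a
    guild (x out of m pairs tested) exceeds the false-discovery rate p0.
    """
    if not 0.0 < p0 < 1.0:
        raise ValueError("p0 must be in (0, 1)")
    if not 0 <= x <= m:
        raise ValueError("need 0 <= x <= m")
    if x == 0:
        return 1.0
    return float(stats.binom.sf(x - 1, m, p0))


def guild_pairs_tested(g: Guild, size_meaning: str = "pairs") -> int:
    """Number of binomial trials for enrichment: member pairs (default) or members."""
    k = len(g.members)
    if size_meaning == "pairs":
        return k * (k - 1) // 2
    if size_meaning == "members":
        return k
    raise ValueError("size_meaning must be 'pairs' or 'members'")


# -- profiles and profile distance ----------------------------------------

def guild_profile(sample_counts: pd.Series, guilds: list[Guild]) -> GuildProfile:
    """Proportion of a sample's reads attributable to each guild.

    The denominator is the sample's total filtered reads; reads of taxa in no
    guild fall into the explicit unassigned bucket.
    """
    total = float(sample_counts.sum())
    if total <= 0:
        raise ValueError(f"sample {sample_counts.name!r} has zero total reads")
    props: dict[int, float] = {}
    assigned = 0.0
    for g in guilds:
        members = [t for t in g.members if t in sample_counts.index]
        reads = float(sample_counts[members].sum()) if members else 0.0
        props[g.id] = reads / total
        assigned += reads
    return GuildProfile(
        sample_id=str(sample_counts.name),
        proportions=props,
        unassigned=1.0 - assigned / total,
    )


def guild_profiles(table: TaxonCountTable, guilds: list[Guild]) -> pd.DataFrame:
    """Profile every sample; columns are guild ids plus 'unassigned'."""
    rows = {}
    for sid in table.samples:
        p = guild_profile(table.counts.loc[sid], guilds)
        rows[sid] = {**{f"G{gid}": v for gid, v in p.proportions.items()},
                     UNASSIGNED: p.unassigned}
    cols = [f"G{g.id}" for g in guilds] + [UNASSIGNED]
    return pd.DataFrame.from_dict(rows, orient="index")[cols]


def guild_distance(a: GuildProfile, b: GuildProfile) -> float:
    """Euclidean distance ∂ between two guild-proportion vectors.

    Computed over guild coordinates only (unassigned excluded); for
    proportion vectors the distance is bounded by sqrt(2).
    """
    if set(a.proportions) != set(b.proportions):
        raise ValueError("profiles cover different guild lists")
    keys = sorted(a.proportions)
    pa = np.array([a.proportions[k] for k in keys])
    pb = np.array([b.proportions[k] for k in keys])
    return float(np.sqrt(((pa - pb) ** 2).sum()))


def profile_distance_row(a: pd.Series, b: pd.Series) -> float:
    """∂ between two rows of a guild_profiles frame (unassigned excluded)."""
    cols = [c for c in a.index if c != UNASSIGNED]
    diff = a[cols].to_numpy(dtype=float) - b[cols].to_numpy(dtype=float)
    return float(np.sqrt((diff ** 2).sum()))


# -- guild TSV round trip --------------------------------------------------

def write_guilds(guilds: list[Guild], unassigned: list[str], path) -> None:
    rows = []
    for g in sorted(guilds, key=lambda g: g.id):
        for t in sorted(g.members):
            rows.append({
                "guild_id": g.id, "taxon": t, "guild_type": g.guild_type,
                "anchor_flag": t == g.anchor,
            })
    for t in unassigned:
        rows.append({"guild_id": 0, "taxon": t, "guild_type": UNASSIGNED,
                     "anchor_flag": False})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_guilds(path) -> tuple[list[Guild], list[str]]:
    df = pd.read_csv(path, sep="\t")
    guilds = []
    unassigned = list(df.loc[df.guild_id == 0, "taxon"].astype(str))
    for gid, grp in df[df.guild_id != 0].groupby("guild_id"):
        anchors = grp.loc[grp.anchor_flag.astype(bool), "taxon"].astype(str)
        gtype = str(grp.guild_type.iloc[0])
        guilds.append(Guild(
            id=int(gid), members=frozenset(grp.taxon.astype(str)),
            guild_type=gtype, anchor=anchors.iloc[0] if len(anchors) else None,
        ))
    return guilds, unassigned
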