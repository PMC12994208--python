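"""Read-count tables, sample metadata, and the contamination/scope filter chain.

Shotgun sedaDNA profiling yields, per sediment sample, read counts assigned to
plant taxa by a phylogenetic read filter of known accuracy.  This module holds
the two universal containers (taxon-by-sample count table, per-sample
metadata), the read-count confidence model P = fpr**n, and the filters applied
before any downstream ecology: negative-control contamination removal,
non-native discard, taxonomic-rank subsetting and the confidence cut-off.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("sedtaph")

RANKS = frozenset({"class", "order", "family", "tribe", "genus", "other"})
SEDIMENT_CLASSES = frozenset(
    {"clay", "silt", "fine_sand", "medium_sand", "coarse_sand", "other"}
)
#: Per-read false-positive rate of the phylogenetic assignment filter
#: (1 - 0.96 published accuracy).
DEFAULT_FPR = 0.04
#: Negative-control proportion above which a taxon is treated as contamination.
DEFAULT_CONTROL_THRESHOLD = 0.02
#: Assignment-confidence cut-off used to define the analysis scope.
DEFAULT_MIN_P = 1e-4

METADATA_COLUMNS = [
    "sample_id", "core_id", "depth_cm", "sediment_class", "laminated",
    "age_calBP", "age_sd", "security", "domain",
]


@dataclass(frozen=True)
class TaxonRecord:
    """Taxonomic assignment unit: name, rank and European-native status."""

    name: str
    rank: str = "other"
    native_europe: bool = True

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("taxon name must be non-empty")
        if self.rank not in RANKS:
            raise ValueError(f"unknown rank {self.rank!r}; expected one of {sorted(RANKS)}")


@dataclass(frozen=True)
class SampleMetadata:
    """Sedimentological and chronological context of one core sample."""

    sample_id: str
    core_id: str
    depth_cm: float
    sediment_class: str = "other"
    laminated: bool = False
    age_calBP: float | None = None
    age_sd: float | None = None
    security: str = "unknown"
    domain: str = "unknown"

    def __post_init__(self) -> None:
        if self.depth_cm < 0:
            raise ValueError("depth_cm must be >= 0")
        if self.sediment_class not in SEDIMENT_CLASSES:
            raise ValueError(f"unknown sediment class {self.sediment_class!r}")
        if self.age_sd is not None and self.age_sd < 0:
            raise ValueError("age uncertainty must be >= 0")
        if self.security not in {"secure", "insecure", "unknown"}:
            raise ValueError(f"unknown security label {self.security!r}")
        if self.domain not in {"marine", "terrestrial", "unknown"}:
            raise ValueError(f"unknown domain {self.domain!r}")


class TaxonCountTable:
    """Samples x taxa read-count matrix with optional taxonomy annotations.

    Wraps a pandas DataFrame (index = sample ids, columns = taxon names,
    values = non-negative integer read counts).  Taxonomy records are kept in
    a parallel mapping; taxa without a record default to rank 'other',
    native_europe True.
    """

    def __init__(
        self,
        counts: pd.DataFrame,
        taxonomy: Mapping[str, TaxonRecord] | None = None,
        drop_empty_taxa: bool = True,
    ) -> None:
        counts = counts.copy()
        if counts.index.has_duplicates:
            raise ValueError("duplicate sample ids in count table")
        if counts.columns.has_duplicates:
            raise ValueError("duplicate taxon columns in count table")
        arr = counts.to_numpy()
        if arr.size and (np.asarray(arr) < 0).any():
            raise ValueError("read counts must be non-negative")
        if drop_empty_taxa:
            empty = counts.columns[(counts.sum(axis=0) == 0)]
            if len(empty):
                logger.info("dropping %d taxa with zero counts in all samples", len(empty))
                counts = counts.drop(columns=empty)
        self.counts = counts.astype(np.int64)
        self.taxonomy: dict[str, TaxonRecord] = dict(taxonomy or {})

    # -- basic accessors ---------------------------------------------------
    @property
    def samples(self) -> list[str]:
        return list(self.counts.index)

    @property
    def taxa(self) -> list[str]:
        return list(self.counts.columns)

    def totals(self) -> pd.Series:
        """Per-sample total read count."""
        return self.counts.sum(axis=1)

    def frequencies(self) -> pd.DataFrame:
        """Per-sample relative frequencies count / sample total (0 where empty)."""
        tot = self.totals().to_numpy(dtype=float)[:, None]
        with np.errstate(invalid="ignore", divide="ignore"):
            freq = self.counts.to_numpy(dtype=float) / tot
        freq = np.where(tot > 0, freq, 0.0)
        return pd.DataFrame(freq, index=self.counts.index, columns=self.counts.columns)

    def record(self, taxon: str) -> TaxonRecord:
        return self.taxonomy.get(taxon, TaxonRecord(taxon))

    def subset_taxa(self, keep: Iterable[str]) -> "TaxonCountTable":
        keep = [t for t in self.taxa if t in set(keep)]
        return TaxonCountTable(self.counts[keep], self.taxonomy, drop_empty_taxa=False)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, TaxonCountTable) and self.counts.equals(other.counts)

    def __repr__(self) -> str:
        return f"TaxonCountTable({len(self.samples)} samples x {len(self.taxa)} taxa)"


# -- confidence model ------------------------------------------------------

def assign_confidence(n: int, fpr: float = DEFAULT_FPR) -> float:
    """P-value of a taxonomic assignment supported by ``n`` independent reads.

    Each read passes the assignment filter wrongly with probability ``fpr``,
    so the chance all ``n`` supporting reads are false positives is fpr**n.
    Monotone non-increasing in ``n``; n = 0 carries no evidence (P = 1).
    """
    if n < 0:
        raise ValueError("read count must be >= 0")
    if not 0.0 <= fpr <= 1.0:
        raise ValueError("fpr must be in [0, 1]")
    return float(fpr) ** int(n)


# -- filters ---------------------------------------------------------------

def filter_negative_control(
    table: TaxonCountTable,
    control: TaxonCountTable,
    threshold: float = DEFAULT_CONTROL_THRESHOLD,
    mode: str = "per-batch",
) -> TaxonCountTable:
    """Remove taxa exceeding ``threshold`` of a negative-control library.

    A taxon is removed when its proportion of the control library's own total
    read count is strictly greater than ``threshold``.  ``mode='per-batch'``
    applies the rule to each control sample (row) separately and removes a
    taxon flagged in any batch; ``mode='pooled'`` sums all control rows first.
    An empty control (total 0) cannot flag anything: a warning is issued and
    the table is returned unchanged.
    """
    if mode not in {"per-batch", "pooled"}:
        raise ValueError("mode must be 'per-batch' or 'pooled'")
    ctl = control.counts
    if ctl.to_numpy().sum() == 0:
        warnings.warn("negative control has zero total reads; no taxa removed")
        return table
    if mode == "pooled":
        ctl = ctl.sum(axis=0).to_frame().T
    tot = ctl.sum(axis=1).to_numpy(dtype=float)
    nonempty = tot > 0
    prop = ctl.to_numpy(dtype=float)[nonempty] / tot[nonempty, None]
    flagged = ctl.columns[(prop > threshold).any(axis=0)]
    removed = [t for t in table.taxa if t in set(flagged)]
    if removed:
        logger.info("negative-control filter removed %d taxa", len(removed))
    keep = [t for t in table.taxa if t not in set(flagged)]
    return table.subset_taxa(keep)


def subset_scope(
    table: TaxonCountTable,
    min_p: float = DEFAULT_MIN_P,
    allowed_ranks: Iterable[str] = RANKS,
    fpr: float = DEFAULT_FPR,
) -> TaxonCountTable:
    """Restrict the table to the analysis scope.

    Keeps taxa that are native to Europe, of an allowed taxonomic rank, and
    whose total-count assignment confidence satisfies fpr**n < ``min_p``.
    """
    if not 0.0 < min_p <= 1.0:
        raise ValueError("min_p must be in (0, 1]")
    allowed = set(allowed_ranks)
    unknown = allowed - RANKS
    if unknown:
        raise ValueError(f"unknown ranks {sorted(unknown)}")
    totals = table.counts.sum(axis=0)
    keep = []
    for taxon in table.taxa:
        rec = table.record(taxon)
        if not rec.native_europe or rec.rank not in allowed:
            continue
        if assign_confidence(int(totals[taxon]), fpr) < min_p:
            keep.append(taxon)
    return table.subset_taxa(keep)


# -- text I/O --------------------------------------------------------------

def read_counts(path: str | Path, taxonomy_path: str | Path | None = None) -> TaxonCountTable:
    """Read a tab-separated samples x taxa count table.

    First column holds sample ids, remaining columns one taxon each.  An
    optional taxonomy sidecar TSV (columns taxon, rank, native_europe)
    supplies ranks and native flags.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.columns.has_duplicates:
        raise ValueError(f"duplicate taxon columns in {path}")
    taxonomy = read_taxonomy(taxonomy_path) if taxonomy_path is not None else None
    return TaxonCountTable(df, taxonomy)


def write_counts(table: TaxonCountTable, path: str | Path) -> None:
    table.counts.to_csv(path, sep="\t", index_label="sample_id")


def read_taxonomy(path: str | Path) -> dict[str, TaxonRecord]:
    df = pd.read_csv(path, sep="\t")
    recs = {}
    for row in df.itertuples(index=False):
        recs[str(row.taxon)] = TaxonRecord(
            name=str(row.taxon),
            rank=str(row.rank),
            native_europe=_as_bool(row.native_europe),
        )
    return recs


def write_taxonomy(taxonomy: Mapping[str, TaxonRecord], path: str | Path) -> None:
    rows = [
        {"taxon": r.name, "rank": r.rank, "native_europe": r.native_europe}
        for r in taxonomy.values()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_metadata(path: str | Path) -> list[SampleMetadata]:
    """Read per-sample metadata TSV (columns as in METADATA_COLUMNS)."""
    df = pd.read_csv(path, sep="\t")
    out = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        out.append(
            SampleMetadata(
                sample_id=str(d["sample_id"]),
                core_id=str(d["core_id"]),
                depth_cm=float(d["depth_cm"]),
                sediment_class=str(d.get("sediment_class", "other") or "other"),
                laminated=_as_bool(d.get("laminated", False)),
                age_calBP=_as_float_or_none(d.get("age_calBP")),
                age_sd=_as_float_or_none(d.get("age_sd")),
                security=str(d.get("security") or "unknown"),
                domain=str(d.get("domain") or "unknown"),
            )
        )
    _check_depth_unique(out)
    return out


def write_metadata(metadata: Sequence[SampleMetadata], path: str | Path) -> None:
    rows = []
    for m in metadata:
        rows.append({
            "sample_id": m.sample_id, "core_id": m.core_id, "depth_cm": m.depth_cm,
            "sediment_class": m.sediment_class, "laminated": m.laminated,
            "age_calBP": m.age_calBP, "age_sd": m.age_sd,
            "security": m.security, "domain": m.domain,
        })
    pd.DataFrame(rows, columns=METADATA_COLUMNS).to_csv(path, sep="\t", index=False)


def _check_depth_unique(metadata: Sequence[SampleMetadata]) -> None:
    seen: dict[tuple[str, float], str] = {}
    for m in metadata:
        key = (m.core_id, m.depth_cm)
        if key in seen:
            raise ValueError(
                f"duplicate depth {m.depth_cm} cm in core {m.core_id} "
                f"({seen[key]} vs {m.sample_id})"
            )
        seen[key] = m.sample_id


def _as_bool(v: object) -> bool:
    if isinstance(v, str):
        return v.strip().lower() in {"true", "1", "yes", "t"}
    if v is None or (isinstance(v, float) and np.isnan(v)):
        return False
    return bool(v)


def _as_float_or_none(v: object) -> float | None:
    if v is None or v == "":
        return None
    f = float(v)  # type: ignore[arg-type]
    return None if np.isnan(f) else f
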