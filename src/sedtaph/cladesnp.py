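"""Clade support from exclusively shared SNPs in a gap-concatenated alignment.

An ancient (sedaDNA) consensus row sits in a multi-taxon alignment built by
concatenating read alignments with 5-base gap separators.  Each polymorphic
column where the ancient row is covered is a SNP site; the reference taxa
matching the ancient state form its sharing set, and a site whose sharing
set is a single taxon exclusively supports a clade uniting that taxon with
the ancient sequence.  Before counting, a damage/quality filter chain masks
likely artefacts in the ancient row: terminal bases of each read block
(deamination-prone ends), singleton states (private to the ancient row),
transitions relative to the reference plurality (C<->T / G<->A, the damage
classes), and optionally columns with incomplete reference data.
"""

from __future__ import annotations

import logging
import re
from collections import Counter
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("sedtaph")

GAP = "-"
MISSING = {"-", "N"}
TRANSITIONS = {("C", "T"), ("T", "C"), ("G", "A"), ("A", "G")}
#: Gap-run length that separates concatenated read blocks in the ancient row.
BLOCK_SEPARATOR_LEN = 5


@dataclass
class SnpSite:
    position: int                 # 0-based column
    states: dict[str, str]        # covered taxa -> base (uppercase)
    ancient_state: str
    sharing_set: frozenset[str]   # reference taxa matching the ancient state
    is_singleton_in_ancient: bool
    is_transition_in_ancient: bool

    @property
    def position_1based(self) -> int:
        return self.position + 1


class ConcatAlignment:
    """Equal-length aligned rows over {A, C, G, T, N, -} with one ancient row."""

    def __init__(self, names: list[str], seqs: list[str], ancient: str) -> None:
        if len(names) != len(seqs):
            raise ValueError("names and sequences differ in number")
        lengths = {len(s) for s in seqs}
        if len(lengths) > 1:
            raise ValueError("alignment rows differ in length")
        if ancient not in names:
            raise ValueError(f"ancient row {ancient!r} not in alignment")
        self.names = list(names)
        self.ancient = ancient
        self.matrix = np.array([list(s.upper()) for s in seqs], dtype="U1")

    @classmethod
    def from_fasta(cls, path: str | Path, ancient: str) -> "ConcatAlignment":
        records = list(SeqIO.parse(str(path), "fasta"))
        return cls([r.id for r in records], [str(r.seq) for r in records], ancient)

    def to_fasta(self, path: str | Path) -> None:
        records = [SeqRecord(Seq("".join(row)), id=name, description="")
                   for name, row in zip(self.names, self.matrix)]
        SeqIO.write(records, str(path), "fasta")

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    @property
    def reference_names(self) -> list[str]:
        return [n for n in self.names if n != self.ancient]

    def row(self, name: str) -> np.ndarray:
        return self.matrix[self.names.index(name)]

    def read_blocks(self) -> list[tuple[int, int]]:
        """Half-open [start, end) intervals of the ancient row between gap
        runs of length >= BLOCK_SEPARATOR_LEN."""
        seq = "".join(self.row(self.ancient))
        blocks = []
        pos = 0
        for part in re.split(f"({GAP}{{{BLOCK_SEPARATOR_LEN},}})", seq):
            if part and not set(part) <= {GAP}:
                blocks.append((pos, pos + len(part)))
            pos += len(part)
        return blocks

    def copy(self) -> "ConcatAlignment":
        out = ConcatAlignment.__new__(ConcatAlignment)
        out.names = list(self.names)
        out.ancient = self.ancient
        out.matrix = self.matrix.copy()
        return out


# -- SNP discovery ---------------------------------------------------------

def find_snp_sites(aln: ConcatAlignment) -> list[SnpSite]:
    """Polymorphic columns where the ancient row is covered.

    A column is a SNP site when the taxa covered there (non-gap, non-N,
    ancient included) show at least two distinct states.  The sharing set is
    the reference taxa whose state equals the ancient state.
    """
    anc_idx = aln.names.index(aln.ancient)
    sites = []
    for col in range(aln.length):
        column = aln.matrix[:, col]
        anc = column[anc_idx]
        if anc in MISSING:
            continue
        states = {aln.names[i]: column[i] for i in range(len(aln.names))
                  if column[i] not in MISSING}
        if len(set(states.values())) < 2:
            continue
        sharing = frozenset(n for n, s in states.items()
                            if n != aln.ancient and s == anc)
        plurality = _plurality_ref_state(states, aln.ancient)
        is_transition = plurality is None or (
            plurality != anc and (anc, plurality) in TRANSITIONS)
        sites.append(SnpSite(
            position=col, states=states, ancient_state=str(anc),
            sharing_set=sharing,
            is_singleton_in_ancient=len(sharing) == 0,
            is_transition_in_ancient=is_transition,
        ))
    return sites


def _plurality_ref_state(states: dict[str, str], ancient: str) -> str | None:
    """Most common reference state at a column; None on a tie (conservative)."""
    ref = Counter(s for n, s in states.items() if n != ancient)
    if not ref:
        return None
    top = ref.most_common()
    if len(top) > 1 and top[0][1] == top[1][1]:
        return None
    return top[0][0]


def clade_support_counts(sites: list[SnpSite]) -> dict[str, int]:
    """Per-reference-taxon count of SNP sites exclusively shared with the ancient row."""
    counts: Counter[str] = Counter()
    for s in sites:
        if len(s.sharing_set) == 1:
            counts[next(iter(s.sharing_set))] += 1
    return dict(counts)


# -- damage / quality filter chain ----------------------------------------

def filter_alignment(
    aln: ConcatAlignment,
    clip: int = 5,
    drop_singletons: bool = True,
    drop_transitions: bool = True,
    require_complete: bool = False,
) -> ConcatAlignment:
    """Mask damage-suspect positions of the ancient row (in order):

    1. clip: ``clip`` bases at each end of every read block (a block shorter
       than 2*clip is wholly masked, logged);
    2. singleton sites: ancient state shared by no reference taxon;
    3. transition sites: ancient differs from the reference plurality state
       by C<->T or G<->A (plurality ties masked, conservative);
    4. optionally, columns where any reference row is gap or N.

    Masked positions are set to 'N' in the ancient row; reference rows are
    untouched.  Returns a new alignment.
    """
    if clip < 0:
        raise ValueError("clip must be >= 0")
    out = aln.copy()
    anc_idx = out.names.index(out.ancient)
    anc = out.matrix[anc_idx]
    for start, end in aln.read_blocks():
        if end - start <= 2 * clip:
            logger.info("read block %d-%d shorter than 2*clip; fully masked", start, end)
            _mask_range(anc, start, end)
        else:
            _mask_range(anc, start, start + clip)
            _mask_range(anc, end - clip, end)
    if drop_singletons or drop_transitions:
        for s in find_snp_sites(out):
            if drop_singletons and s.is_singleton_in_ancient:
                anc[s.position] = "N"
            elif drop_transitions and s.is_transition_in_ancient:
                anc[s.position] = "N"
    if require_complete:
        refs = np.delete(out.matrix, anc_idx, axis=0)
        incomplete = np.isin(refs, list(MISSING)).any(axis=0)
        covered = ~np.isin(anc, list(MISSING))
        anc[incomplete & covered] = "N"
    return out


def _mask_range(row: np.ndarray, start: int, end: int) -> None:
    seg = row[start:end]
    seg[~np.isin(seg, list(MISSING))] = "N"


def filter_stage_report(aln: ConcatAlignment, clip: int = 5) -> dict[str, dict[str, int]]:
    """Exclusive-share counts per taxon at each successive filter stage."""
    stages = {
        "raw": aln,
        "clipped": filter_alignment(aln, clip=clip, drop_singletons=False,
                                    drop_transitions=False),
        "no_singletons": filter_alignment(aln, clip=clip, drop_transitions=False),
        "no_transitions": filter_alignment(aln, clip=clip),
        "complete_only": filter_alignment(aln, clip=clip, require_complete=True),
    }
    return {name: clade_support_counts(find_snp_sites(a))
            for name, a in stages.items()}
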