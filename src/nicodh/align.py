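"""Pairwise alignment utilities: global alignment, anchor-position mapping,
gap-threshold column trimming, and nearest-anchor clade assignment.

These are the implemented stand-ins for the usual MSA/tree workflow on large
Ni-CODH datasets: instead of a progressive multiple alignment and an ML tree,
each query is globally aligned to one reference anchor per clade, assigned the
clade of its best-scoring anchor, and read off against that anchor's named
cluster positions.  Alignment itself is delegated to Biopython's
``PairwiseAligner`` (Needleman–Wunsch with affine gaps) under a BLOSUM62 table
whose ``X`` row/column is zeroed so unknown residues are scored neutrally.

Gap convention: opening a gap costs 11 for its first residue plus 1 per
additional residue (a length-1 gap costs 11, length-3 costs 13).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Optional, Sequence

import numpy as np
from Bio.Align import PairwiseAligner, substitution_matrices

from .anchors import AnchorProfile

DEFAULT_GAP_OPEN = 11
DEFAULT_GAP_EXTEND = 1

#: score-margin below which a nearest-anchor clade call is flagged ambiguous
DEFAULT_AMBIGUITY_DELTA = 5.0


@lru_cache(maxsize=None)
def _blosum62_x_neutral():
    mat = substitution_matrices.load("BLOSUM62").copy()
    for letter in mat.alphabet:
        mat["X", letter] = 0.0
        mat[letter, "X"] = 0.0
    return mat


@lru_cache(maxsize=8)
def _aligner(gap_open: float, gap_extend: float) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = _blosum62_x_neutral()
    aligner.open_gap_score = -float(gap_open)
    aligner.extend_gap_score = -float(gap_extend)
    return aligner


def _gap_cost(length: int, gap_open: float, gap_extend: float) -> float:
    if length <= 0:
        return 0.0
    return gap_open + gap_extend * (length - 1)


def global_align(
    seq_a: str,
    seq_b: str,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> tuple[str, str, float]:
    """Optimal global alignment of two protein sequences.

    Returns ``(aligned_a, aligned_b, score)`` where the aligned strings carry
    ``-`` gap characters.  Deterministic: the aligner's first optimal traceback
    is always returned.  An empty sequence yields the all-gap alignment with
    score ``-(gap_open + gap_extend*(len-1))`` against the other.
    """
    if not seq_a and not seq_b:
        return "", "", 0.0
    if not seq_a or not seq_b:
        full = seq_a or seq_b
        gaps = "-" * len(full)
        score = -_gap_cost(len(full), gap_open, gap_extend)
        if not seq_a:
            return gaps, full, score
        return full, gaps, score
    aln = _aligner(gap_open, gap_extend).align(seq_a, seq_b)[0]
    return str(aln[0]), str(aln[1]), float(aln.score)


def global_align_score(
    seq_a: str,
    seq_b: str,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> float:
    """Score-only variant of :func:`global_align` (skips traceback)."""
    if not seq_a or not seq_b:
        return global_align(seq_a, seq_b, gap_open, gap_extend)[2]
    return float(_aligner(gap_open, gap_extend).score(seq_a, seq_b))


@dataclass
class PositionMap:
    """Mapping of one anchor's coordinates onto one query sequence.

    ``coords[i]`` is the 1-based query coordinate aligned to anchor position
    ``i`` (1-based), or ``None`` when that anchor column is deleted in the
    query.  ``named`` resolves the anchor's named cluster positions the same
    way.
    """

    query_id: str
    anchor_clade: str
    coords: list[Optional[int]]  # index 0 unused; 1..len(anchor)
    named: dict[str, Optional[int]]
    query_length: int

    def get(self, anchor_pos: int) -> Optional[int]:
        return self.coords[anchor_pos]

    def first_mapped_at_or_after(self, anchor_pos: int) -> Optional[int]:
        for p in range(anchor_pos, len(self.coords)):
            if self.coords[p] is not None:
                return self.coords[p]
        return None

    def last_mapped_at_or_before(self, anchor_pos: int) -> Optional[int]:
        for p in range(anchor_pos, 0, -1):
            if self.coords[p] is not None:
                return self.coords[p]
        return None

    def query_span(self, anchor_start: int, anchor_end: int) -> tuple[int, int] | None:
        """Query coordinate span covered by anchor columns [start, end].

        Returns the (min, max) query coordinates aligned inside the span, so
        query insertions between mapped columns are included.  ``None`` when
        every column of the span is deleted in the query.
        """
        mapped = [
            self.coords[p]
            for p in range(max(1, anchor_start), min(len(self.coords) - 1, anchor_end) + 1)
            if self.coords[p] is not None
        ]
        if not mapped:
            return None
        return min(mapped), max(mapped)


def map_anchor_positions(query_id: str, query_seq: str, anchor: AnchorProfile,
                         gap_open: float = DEFAULT_GAP_OPEN,
                         gap_extend: float = DEFAULT_GAP_EXTEND) -> PositionMap:
    """Globally align *query* to *anchor* and map every anchor position.

    Each named anchor position maps to the query column aligned to it, or to
    ``None`` ("absent") when it falls in a deletion.
    """
    coords: list[Optional[int]] = [None] * (len(anchor.sequence) + 1)
    if query_seq:
        aln = _aligner(gap_open, gap_extend).align(anchor.sequence, query_seq)[0]
        anchor_blocks, query_blocks = aln.aligned
        for (astart, aend), (qstart, _qend) in zip(anchor_blocks, query_blocks):
            for off in range(aend - astart):
                coords[astart + off + 1] = qstart + off + 1
    named = {
        name: coords[pos] for name, pos in anchor.named_positions().items()
    }
    return PositionMap(
        query_id=query_id,
        anchor_clade=anchor.clade,
        coords=coords,
        named=named,
        query_length=len(query_seq),
    )


def trim_alignment_columns(
    msa: Sequence[str], gap_threshold: float = 0.9
) -> list[int]:
    """Column indices (0-based) retained at the given gap threshold.

    A column is retained iff its fraction of non-gap characters is >= the
    threshold — the convention used when trimming a protein MSA before tree
    building.  Rows must be equal length.
    """
    if not 0.0 <= gap_threshold <= 1.0:
        raise ValueError("gap_threshold must be in [0, 1]")
    if not msa:
        return []
    lengths = {len(row) for row in msa}
    if len(lengths) != 1:
        raise ValueError("alignment rows must have equal length")
    arr = np.array([list(row) for row in msa])
    nongap_frac = (arr != "-").mean(axis=0)
    return [int(i) for i in np.nonzero(nongap_frac >= gap_threshold)[0]]


@dataclass(frozen=True)
class CladeCall:
    clade: str
    score: float
    margin: float
    ambiguous: bool


def assign_clade(
    query_seq: str,
    anchors: Sequence[AnchorProfile],
    ambiguity_delta: float = DEFAULT_AMBIGUITY_DELTA,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> CladeCall:
    """Nearest-anchor clade assignment.

    The query is scored against every anchor; the clade of the best score
    wins.  When the top-two margin is below *ambiguity_delta* (or the top
    scores tie exactly), the call is flagged ambiguous; exact ties resolve to
    the alphabetically first clade.
    """
    if not anchors:
        raise ValueError("at least one anchor profile is required")
    scored = sorted(
        (
            (-global_align_score(query_seq, a.sequence, gap_open, gap_extend), a.clade)
            for a in anchors
        ),
    )
    best_neg, best_clade = scored[0]
    best = -best_neg
    if len(scored) == 1:
        return CladeCall(best_clade, best, float("inf"), False)
    margin = best - (-scored[1][0])
    return CladeCall(best_clade, best, margin, margin < ambiguity_delta)
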