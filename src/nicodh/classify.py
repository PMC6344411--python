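"""Structural-group classification of Ni-CODH sequences.

Anaerobic Ni-CODHs carry a catalytic C-cluster (one His plus five Cys sites),
a B-cluster [4Fe-4S] cubane (four Cys), a subunit-interface D-cluster whose
Cys spacing falls into three motif types, an acid–base catalyst pair
(canonically His/Lys), and — in the Cdh-type clade A only — two further
cubanes (E- and F-clusters).  Reading the residue states at these positions,
plus a handful of accessory motifs (N-/C-terminal Cys motifs, His-rich
His-X-His repeats, Cys×4 insertions), places every sequence into one of 24
structural groups spread over clades A–G, or into "others" when no labeled
signature row matches.

D-cluster motif types::

    type I    Cys-X-X-Cys-Cys
    type II   Cys-(X)7..13-Cys-Cys
    type III  Cys-X-X-Cys-(X)5-Cys

with X any residue; regions holding one or no Cys have no D-cluster motif.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .align import PositionMap
from .anchors import AnchorProfile

D_TYPES = ("I", "II", "III")

#: slack (residues on each side) added when reading the D-region off a query
D_REGION_SLACK = 5

#: window (residues) within which terminal Cys motifs are counted
TERMINAL_CYS_WINDOW = 20
#: minimum His count for a His-rich terminal extension
HIS_RICH_FLOOR = 4
#: window for a Cys×4 insertion between the E- and F-clusters
EF_INSERTION_WINDOW = 30
#: length excess over the anchor that flags a fusion protein
FUSION_EXCESS = 200

_D_PATTERNS = (
    ("I", re.compile(r"C..CC")),
    ("III", re.compile(r"C..C.{5}C")),
    ("II", re.compile(r"C.{7,13}CC")),
)

_C_COMPLETE = ("H", "C", "C", "C", "C", "C")

#: the 24 structural-group signature rows: clade, D-type (None = no motif),
#: C-cluster 6-tuple (His, Cys1..Cys5), acid–base pair, E/F state
#: ("complete" / "none" / "e_only" / None for CooS-type clades), accessory motifs.
STRUCTURAL_GROUPS: dict[str, dict] = {
    "A-1": dict(clade="A", d="I", c=_C_COMPLETE, ab=("H", "K"), ef="complete", motifs=()),
    "A-2": dict(clade="A", d=None, c=_C_COMPLETE, ab=("H", "K"), ef="complete", motifs=()),
    "A-3": dict(clade="A", d=None, c=_C_COMPLETE, ab=("H", "K"), ef="none", motifs=()),
    "A-4": dict(clade="A", d=None, c=("D", "P", "C", "C", "C", "C"), ab=("Q", "R"),
                ef="complete", motifs=()),
    "A-5": dict(clade="A", d=None, c=_C_COMPLETE, ab=("H", "K"), ef="complete",
                motifs=("ef_cys4x2",)),
    "A-6": dict(clade="A", d=None, c=("N", "S", "C", "C", "C", "C"), ab=("H", "L"),
                ef="e_only", motifs=()),
    "B-1": dict(clade="B", d="II", c=("H", "C", "D", "C", "C", "C"), ab=("H", "K"),
                ef=None, motifs=("nterm_his_rich",)),
    "B-2": dict(clade="B", d="II", c=("H", "C", "D", "C", "C", "C"), ab=("H", "K"),
                ef=None, motifs=()),
    "B-3": dict(clade="B", d="II", c=("H", "C", "D", "C", "C", "C"), ab=("H", "K"),
                ef=None, motifs=("cterm_his_rich",)),
    "B-4": dict(clade="B", d="II", c=_C_COMPLETE, ab=("H", "K"), ef=None, motifs=()),
    "C-1": dict(clade="C", d="II", c=_C_COMPLETE, ab=("Y", "Q"), ef=None,
                motifs=("nterm_cys3",)),
    "C-2": dict(clade="C", d="II", c=_C_COMPLETE, ab=("Y", "Q"), ef=None, motifs=()),
    "C-3": dict(clade="C", d=None, c=_C_COMPLETE, ab=("Y", "Q"), ef=None,
                motifs=("d_single_cys",)),
    "C-4": dict(clade="C", d="II", c=_C_COMPLETE, ab=("Y", "Q"), ef=None,
                motifs=("c_insert_cys4",)),
    "D-1": dict(clade="D", d="III", c=("H", "E", "C", "C", "C", "C"), ab=("Y", "K"),
                ef=None, motifs=()),
    "D-2": dict(clade="D", d="III", c=_C_COMPLETE, ab=("N", "K"), ef=None, motifs=()),
    "D-3": dict(clade="D", d="II", c=_C_COMPLETE, ab=("Y", "K"), ef=None,
                motifs=("nterm_cys3",)),
    "D-4": dict(clade="D", d="II", c=_C_COMPLETE, ab=("Y", "K"), ef=None, motifs=()),
    "E-1": dict(clade="E", d="II", c=_C_COMPLETE, ab=("H", "K"), ef=None, motifs=()),
    "E-2": dict(clade="E", d="III", c=_C_COMPLETE, ab=("H", "K"), ef=None, motifs=()),
    "E-3": dict(clade="E", d="II", c=_C_COMPLETE, ab=("H", "K"), ef=None,
                motifs=("nterm_cys2",)),
    "F-1": dict(clade="F", d="II", c=_C_COMPLETE, ab=("H", "K"), ef=None, motifs=()),
    "F-2": dict(clade="F", d="II", c=_C_COMPLETE, ab=("H", "K"), ef=None,
                motifs=("nterm_cys2",)),
    "G-1": dict(clade="G", d="III", c=("H", "T", "C", "C", "C", "C"), ab=("Y", "K"),
                ef=None, motifs=()),
}

GROUP_LABELS = tuple(STRUCTURAL_GROUPS)
OTHERS = "others"


def classify_d_region(region: str) -> Optional[str]:
    """Classify a D-cluster region string into motif type I, II, III, or None.

    Precedence is I > III > II (most specific first); the spacer ``X`` matches
    any residue.  Empty regions and regions matching no pattern return None.
    """
    for dtype, pat in _D_PATTERNS:
        if pat.search(region):
            return dtype
    return None


@dataclass
class StructuralSignature:
    """Residue states read off one query at its anchor's named positions."""

    d_type: Optional[str] = None
    c_cluster: tuple = ("absent",) * 6  # (His site, Cys1..Cys5)
    acid_base: tuple = ("absent", "absent")
    b_complete: bool = False
    e_complete: Optional[bool] = None  # None when the clade has no E/F clusters
    f_complete: Optional[bool] = None
    extra_ef_cys4_count: int = 0
    nterm_cys_count: int = 0
    cterm_cys_count: int = 0
    nterm_his_rich: bool = False
    cterm_his_rich: bool = False
    c_insertion_cys4: bool = False
    fusion: bool = False


@dataclass
class GroupAssignment:
    protein_id: str
    clade: str
    group_label: str
    signature: StructuralSignature
    clade_ambiguous: bool = False
    notes: str = ""


def _residue(query: str, coord: Optional[int]) -> str:
    return "absent" if coord is None else query[coord - 1]


def _region_string(query: str, pmap: PositionMap, a_start: int, a_end: int) -> str:
    span = pmap.query_span(a_start, a_end)
    if span is None:
        return ""
    return query[span[0] - 1 : span[1]]


def extract_site_signature(query: str, pmap: PositionMap,
                           anchor: AnchorProfile) -> StructuralSignature:
    """Read the core signature fields (D/B/C clusters, acid–base pair)."""
    sig = StructuralSignature()
    named = pmap.named
    sig.c_cluster = tuple(
        _residue(query, named[k])
        for k in ("c_his", "c_cys1", "c_cys2", "c_cys3", "c_cys4", "c_cys5")
    )
    sig.acid_base = (_residue(query, named["ab_his"]), _residue(query, named["ab_lys"]))
    sig.b_complete = all(
        _residue(query, named[f"b{i}"]) == "C" for i in range(1, 5)
    )
    if anchor.has_ef:
        sig.e_complete = all(
            _residue(query, named[f"e{i}"]) == "C" for i in range(1, 5)
        )
        sig.f_complete = all(
            _residue(query, named[f"f{i}"]) == "C" for i in range(1, 5)
        )
    d_start, d_end = anchor.d_region_span
    region = _region_string(query, pmap, d_start - D_REGION_SLACK, d_end + D_REGION_SLACK)
    sig.d_type = classify_d_region(region)
    return sig


def _max_window_count(region: str, letter: str, window: int) -> int:
    hits = [i for i, ch in enumerate(region) if ch == letter]
    best = 0
    j = 0
    for i in range(len(hits)):
        while hits[i] - hits[j] >= window:
            j += 1
        best = max(best, i - j + 1)
    return best


def _his_rich(region: str) -> bool:
    if region.count("H") < HIS_RICH_FLOOR:
        return False
    matches = [
        i for i in range(len(region) - 2)
        if region[i] == "H" and region[i + 2] == "H"
    ]
    return any(b - a <= 2 for a, b in zip(matches, matches[1:]))


def detect_terminal_motifs(query: str, pmap: PositionMap,
                           anchor: AnchorProfile) -> tuple[int, int, bool, bool]:
    """Accessory motifs in the N-/C-terminal extension regions.

    Returns ``(nterm_cys_count, cterm_cys_count, nterm_his_rich,
    cterm_his_rich)``.  The Cys count is the maximal number of Cys inside any
    20-residue window of the extension, reported when >= 2 and capped at 4.
    His-rich means >= 4 His plus at least two mutually overlapping His-X-His
    matches.
    """
    q_core_start = pmap.first_mapped_at_or_after(anchor.core_start)
    q_core_end = pmap.last_mapped_at_or_before(anchor.core_end)
    nterm = query[: q_core_start - 1] if q_core_start else ""
    cterm = query[q_core_end:] if q_core_end else ""

    def cys_count(region: str) -> int:
        c = _max_window_count(region, "C", TERMINAL_CYS_WINDOW)
        return min(c, 4) if c >= 2 else 0

    return cys_count(nterm), cys_count(cterm), _his_rich(nterm), _his_rich(cterm)


def detect_insertions(query: str, pmap: PositionMap,
                      anchor: AnchorProfile) -> tuple[bool, int, bool]:
    """Cys×4 insertions and fusion flag.

    * ``c_insertion_cys4``: >= 4 Cys strictly between the acid–base His-site
      column and the C-cluster His column (the C-4 signature).
    * ``extra_ef_cys4_count``: disjoint <=30-residue windows holding >= 4 Cys
      strictly between the E- and F-cluster spans (clade A only; the A-5
      signature counts two).
    * ``fusion``: query is more than 200 residues longer than the anchor.
    """

    def between(qa: Optional[int], qb: Optional[int]) -> str:
        if qa is None or qb is None:
            return ""
        lo, hi = (qa, qb) if qa < qb else (qb, qa)
        return query[lo : hi - 1]  # strictly between

    named = pmap.named
    c_insertion = between(named["ab_his"], named["c_his"]).count("C") >= 4

    ef_count = 0
    if anchor.has_ef:
        span = between(named["e4"], named["f1"])
        cys = [i for i, ch in enumerate(span) if ch == "C"]
        i = 0
        while i < len(cys):
            j = i
            while j + 1 < len(cys) and cys[j + 1] - cys[i] < EF_INSERTION_WINDOW:
                j += 1
            if j - i + 1 >= 4:
                ef_count += 1
                i = j + 1
            else:
                i += 1

    fusion = len(query) > len(anchor.sequence) + FUSION_EXCESS
    return c_insertion, ef_count, fusion


def build_signature(query: str, pmap: PositionMap,
                    anchor: AnchorProfile) -> StructuralSignature:
    """Full signature: core sites plus terminal motifs and insertions."""
    sig = extract_site_signature(query, pmap, anchor)
    (sig.nterm_cys_count, sig.cterm_cys_count,
     sig.nterm_his_rich, sig.cterm_his_rich) = detect_terminal_motifs(query, pmap, anchor)
    (sig.c_insertion_cys4, sig.extra_ef_cys4_count,
     sig.fusion) = detect_insertions(query, pmap, anchor)
    return sig


def assign_structural_group(clade: str, sig: StructuralSignature,
                            protein_id: str = "",
                            clade_ambiguous: bool = False) -> GroupAssignment:
    """Apply the per-clade decision rows; unmatched signatures become "others".

    Total function: every (clade, signature) pair yields exactly one label.
    """
    label = _decide(clade, sig)
    return GroupAssignment(
        protein_id=protein_id,
        clade=clade,
        group_label=label,
        signature=sig,
        clade_ambiguous=clade_ambiguous,
    )


def _decide(clade: str, s: StructuralSignature) -> str:
    c_std = s.c_cluster == _C_COMPLETE
    if not s.b_complete:
        return OTHERS
    if clade == "A":
        ef_full = bool(s.e_complete) and bool(s.f_complete)
        if s.d_type == "I" and ef_full and c_std and s.acid_base == ("H", "K"):
            return "A-1"
        if s.d_type is None:
            if ef_full and c_std and s.acid_base == ("H", "K"):
                if s.extra_ef_cys4_count == 2:
                    return "A-5"
                if s.extra_ef_cys4_count == 0:
                    return "A-2"
                return OTHERS
            if not s.e_complete and not s.f_complete and c_std \
                    and s.acid_base == ("H", "K"):
                return "A-3"
            if ef_full and s.c_cluster == ("D", "P", "C", "C", "C", "C") \
                    and s.acid_base == ("Q", "R"):
                return "A-4"
            if s.e_complete and not s.f_complete \
                    and s.c_cluster == ("N", "S", "C", "C", "C", "C") \
                    and s.acid_base == ("H", "L"):
                return "A-6"
        return OTHERS
    if clade == "B":
        if s.d_type != "II" or s.acid_base != ("H", "K"):
            return OTHERS
        base = tuple(s.c_cluster[i] for i in (0, 1, 3, 4, 5))
        if base != ("H", "C", "C", "C", "C"):
            return OTHERS
        cys2 = s.c_cluster[2]
        if cys2 in ("D", "E") and s.nterm_his_rich and not s.cterm_his_rich:
            return "B-1"
        if cys2 == "D" and s.cterm_his_rich and not s.nterm_his_rich:
            return "B-3"
        if cys2 == "D" and not s.nterm_his_rich and not s.cterm_his_rich:
            return "B-2"
        if cys2 == "C" and not s.nterm_his_rich and not s.cterm_his_rich:
            return "B-4"
        return OTHERS
    if clade == "C":
        if not c_std or s.acid_base != ("Y", "Q"):
            return OTHERS
        if s.d_type == "II":
            if s.c_insertion_cys4:
                return "C-4"
            if s.nterm_cys_count >= 2:
                return "C-1"
            return "C-2"
        if s.d_type is None:
            return "C-3"
        return OTHERS
    if clade == "D":
        if s.d_type == "III":
            if s.c_cluster == ("H", "E", "C", "C", "C", "C") \
                    and s.acid_base == ("Y", "K"):
                return "D-1"
            if c_std and s.acid_base == ("N", "K"):
                return "D-2"
            return OTHERS
        if s.d_type == "II" and c_std and s.acid_base == ("Y", "K"):
            return "D-3" if s.nterm_cys_count >= 2 else "D-4"
        return OTHERS
    if clade == "E":
        if not c_std or s.acid_base != ("H", "K"):
            return OTHERS
        if s.d_type == "III":
            return "E-2"
        if s.d_type == "II":
            return "E-3" if s.nterm_cys_count >= 2 else "E-1"
        return OTHERS
    if clade == "F":
        if s.d_type == "II" and c_std and s.acid_base == ("H", "K"):
            return "F-2" if s.nterm_cys_count >= 2 else "F-1"
        return OTHERS
    if clade == "G":
        if s.d_type == "III" and s.c_cluster == ("H", "T", "C", "C", "C", "C") \
                and s.acid_base == ("Y", "K"):
            return "G-1"
        return OTHERS
    return OTHERS


def classify_protein(protein_id: str, query_seq: str,
                     anchors: Sequence[AnchorProfile],
                     ambiguity_delta: float = 5.0) -> GroupAssignment:
    """Convenience end-to-end call: clade assignment, mapping, classification."""
    from .align import assign_clade, map_anchor_positions

    call = assign_clade(query_seq, anchors, ambiguity_delta=ambiguity_delta)
    anchor = next(a for a in anchors if a.clade == call.clade)
    pmap = map_anchor_positions(protein_id, query_seq, anchor)
    sig = build_signature(query_seq, pmap, anchor)
    return assign_structural_group(call.clade, sig, protein_id=protein_id,
                                   clade_ambiguous=call.ambiguous)
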