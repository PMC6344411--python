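"""Anchor profiles: clade-labeled reference sequences with named cluster positions.

An :class:`AnchorProfile` formalizes, for one phylogenetic clade (A–G), where the
metal-cluster and catalytic residues sit on a reference Ni-CODH sequence: the
D-cluster region (whose Cys spacing defines motif types I/II/III), the four
B-cluster Cys, the six C-cluster sites (His + Cys1..Cys5), the acid–base
catalyst pair (His/Lys sites), and — for Cdh-type clade A only — the four Cys of
each of the E- and F-clusters.  ``core_start``/``core_end`` bound the aligned
core; residues outside them are the N-/C-terminal extension regions searched
for accessory Cys motifs and His-rich repeats.

All coordinates are 1-based inclusive, as in GFF3 and the classifier output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

CLADES = ("A", "B", "C", "D", "E", "F", "G")

#: canonical synthetic scaffold layout (1-based positions on a 650-residue chain)
SCAFFOLD_LENGTH = 650
CORE_START = 41
CORE_END = 610
D_REGION_SPAN = (55, 80)
B_CLUSTER = (110, 118, 126, 134)
E_CLUSTER = (160, 168, 176, 184)
F_CLUSTER = (300, 308, 316, 324)
ACID_BASE = (380, 386)  # (His site, Lys site)
C_CLUSTER = (430, 450, 468, 486, 504, 522)  # (His, Cys1..Cys5)


@dataclass(frozen=True)
class AnchorProfile:
    """A clade reference sequence plus its named cluster positions."""

    clade: str
    sequence: str
    d_region_span: tuple[int, int]
    b_cluster: tuple[int, int, int, int]
    c_cluster: tuple[int, int, int, int, int, int]
    acid_base: tuple[int, int]
    core_start: int
    core_end: int
    e_cluster: Optional[tuple[int, int, int, int]] = None
    f_cluster: Optional[tuple[int, int, int, int]] = None

    def __post_init__(self) -> None:
        if self.clade not in CLADES:
            raise ValueError(f"unknown clade {self.clade!r}")
        n = len(self.sequence)
        for pos in self.all_positions():
            if not 1 <= pos <= n:
                raise ValueError(f"anchor position {pos} outside [1, {n}]")
        if list(self.c_cluster) != sorted(set(self.c_cluster)):
            raise ValueError("c_cluster positions must be strictly increasing")
        if self.core_start > min(self.cluster_positions()):
            raise ValueError("core_start must not exceed the first cluster position")
        if (self.e_cluster is None) != (self.f_cluster is None):
            raise ValueError("E- and F-cluster positions must be given together")

    # -- position bookkeeping -------------------------------------------------

    def cluster_positions(self) -> list[int]:
        """All structurally named single-residue positions (not the span/bounds)."""
        pos = list(self.b_cluster) + list(self.c_cluster) + list(self.acid_base)
        if self.e_cluster:
            pos += list(self.e_cluster) + list(self.f_cluster)
        return pos

    def all_positions(self) -> list[int]:
        return (
            self.cluster_positions()
            + list(self.d_region_span)
            + [self.core_start, self.core_end]
        )

    def named_positions(self) -> dict[str, int]:
        """Flat name -> 1-based anchor coordinate map used by PositionMap."""
        named = {
            "d_start": self.d_region_span[0],
            "d_end": self.d_region_span[1],
            "core_start": self.core_start,
            "core_end": self.core_end,
            "ab_his": self.acid_base[0],
            "ab_lys": self.acid_base[1],
            "c_his": self.c_cluster[0],
        }
        for i, p in enumerate(self.b_cluster, 1):
            named[f"b{i}"] = p
        for i, p in enumerate(self.c_cluster[1:], 1):
            named[f"c_cys{i}"] = p
        if self.e_cluster:
            for i, p in enumerate(self.e_cluster, 1):
                named[f"e{i}"] = p
            for i, p in enumerate(self.f_cluster, 1):
                named[f"f{i}"] = p
        return named

    @property
    def has_ef(self) -> bool:
        return self.e_cluster is not None

    # -- serialization ---------------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AnchorProfile":
        def tup(x):
            return tuple(x) if x is not None else None

        return cls(
            clade=d["clade"],
            sequence=d["sequence"],
            d_region_span=tup(d["d_region_span"]),
            b_cluster=tup(d["b_cluster"]),
            c_cluster=tup(d["c_cluster"]),
            acid_base=tup(d["acid_base"]),
            core_start=d["core_start"],
            core_end=d["core_end"],
            e_cluster=tup(d.get("e_cluster")),
            f_cluster=tup(d.get("f_cluster")),
        )


def save_anchors(anchors: Sequence[AnchorProfile], path: str | Path) -> None:
    """Write anchor profiles to the JSON sidecar format (sorted by clade)."""
    payload = [a.to_dict() for a in sorted(anchors, key=lambda a: a.clade)]
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")


def load_anchors(path: str | Path) -> list[AnchorProfile]:
    payload = json.loads(Path(path).read_text())
    return [AnchorProfile.from_dict(d) for d in payload]
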