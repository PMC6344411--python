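"""Lightweight record types shared across modules."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional


@dataclass(frozen=True)
class ProteinRecord:
    """One amino-acid sequence with identifier and optional genome link."""

    id: str
    sequence: str
    genome_id: Optional[str] = None
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("protein id must be non-empty")


@dataclass(frozen=True)
class HitRecord:
    """One homology-search hit row (subject id, bit score, subject length)."""

    subject_id: str
    bit_score: float
    subject_length: int

    def __post_init__(self) -> None:
        if self.bit_score < 0:
            raise ValueError("bit_score must be >= 0")
        if self.subject_length < 1:
            raise ValueError("subject_length must be >= 1")


@dataclass(frozen=True)
class GenomeMetadata:
    """Assembly-level metadata used for per-species genome selection."""

    genome_id: str
    species_key: str
    assembly_category: str  # reference | representative | na
    assembly_level: str  # complete | chromosome | scaffold | contig
    phylum: str = ""
    family: str = ""
    codh_protein_ids: frozenset[str] = frozenset()
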