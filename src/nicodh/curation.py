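"""Dataset curation filters.

Mirrors the screens applied when assembling a non-redundant Ni-CODH dataset
from homology-search output: drop low-scoring/short hits (HCPs and partial
fragments), collapse duplicate identifiers, keep only sequences whose metal
clusters and catalytic residues are intact in the alignment, and keep one
genome per species per distinct CODH complement (priority: reference >
representative > complete assembly > draft).
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

from .align import PositionMap
from .records import GenomeMetadata, HitRecord, ProteinRecord

MIN_BIT_SCORE = 200.0
MIN_LENGTH = 550

#: named positions that must not be deleted for a sequence to be "complete"
_REQUIRED_KEYS = (
    "d_start", "d_end",
    "b1", "b2", "b3", "b4",
    "c_his", "c_cys1", "c_cys2", "c_cys3", "c_cys4", "c_cys5",
    "ab_his", "ab_lys",
)


def filter_hits(hits: Iterable[HitRecord],
                min_bit_score: float = MIN_BIT_SCORE,
                min_length: int = MIN_LENGTH) -> list[str]:
    """Subject ids retained at the score/length thresholds.

    A hit is kept iff ``bit_score >= min_bit_score`` and ``subject_length >=
    min_length`` (the exclusions are strict ``<``, so boundary values are
    retained).  Duplicate subject ids collapse to one; output is sorted.
    """
    if min_bit_score <= 0 or min_length <= 0:
        raise ValueError("thresholds must be positive")
    kept = {
        h.subject_id
        for h in hits
        if h.bit_score >= min_bit_score and h.subject_length >= min_length
    }
    return sorted(kept)


def deduplicate_proteins(records: Sequence[ProteinRecord]) -> list[ProteinRecord]:
    """One record per identifier, ordering stable by identifier.

    Two records under the same identifier must carry the same sequence;
    conflicting sequences indicate corrupt input and raise.  Distinct
    identifiers with identical sequences are both kept (redundancy is by
    identifier, as in a non-redundant protein database).
    """
    by_id: dict[str, ProteinRecord] = {}
    for rec in records:
        prev = by_id.get(rec.id)
        if prev is None:
            by_id[rec.id] = rec
        elif prev.sequence != rec.sequence:
            raise ValueError(
                f"conflicting sequences under identifier {rec.id!r}"
            )
    return [by_id[k] for k in sorted(by_id)]


def filter_complete_sequences(
    mapped_positions: Mapping[str, PositionMap],
) -> list[str]:
    """Query ids whose D-/B-/C-cluster and acid–base positions all mapped.

    A query is retained iff none of the anchor's required positions aligns to
    a gap; substitutions (non-gap, different residue) are fine.  Output is
    sorted by query id.
    """
    retained = [
        qid
        for qid, pmap in mapped_positions.items()
        if all(pmap.named.get(k) is not None for k in _REQUIRED_KEYS)
    ]
    return sorted(retained)


_CATEGORY_RANK = {"reference": 0, "representative": 1}


def _priority(meta: GenomeMetadata) -> tuple[int, str]:
    rank = _CATEGORY_RANK.get(meta.assembly_category)
    if rank is None:
        rank = 2 if meta.assembly_level == "complete" else 3
    return rank, meta.genome_id


def select_representative_genomes(
    metadata: Sequence[GenomeMetadata],
) -> list[str]:
    """Per species, keep one genome per distinct CODH protein-id set.

    Within each species, genomes are partitioned by their CODH id sets (same
    species is dropped *unless* it contributes different CODH accessions);
    per partition the winner has priority reference > representative >
    complete assembly > draft, ties broken by smallest genome id.  Output is
    sorted by genome id.
    """
    best: dict[tuple[str, frozenset[str]], GenomeMetadata] = {}
    for meta in metadata:
        key = (meta.species_key, frozenset(meta.codh_protein_ids))
        cur = best.get(key)
        if cur is None or _priority(meta) < _priority(cur):
            best[key] = meta
    return sorted(m.genome_id for m in best.values())
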