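"""Directon extraction and genomic-context curation.

A *directon* is a maximal run of adjacent same-strand genes with small
intergenic gaps — the operon-like unit used to read a CODH gene's genomic
neighborhood.  Here a directon is anchored at a CODH gene and extended in
both directions while the next gene shares the strand, the intergenic gap is
at most 300 bp, and at most 15 genes are added per side.  The curated
*context locus* of a CODH gene is its directon plus any contiguous flanking
genes carrying significantly enriched COGs, added serially on each side
regardless of strand or distance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import pandas as pd

DEFAULT_MAX_GAP_BP = 300
DEFAULT_MAX_SIDE_GENES = 15


@dataclass(frozen=True)
class GeneRecord:
    """One CDS row of a replicon, 1-based inclusive coordinates."""

    genome_id: str
    replicon_id: str
    index: int
    start: int
    end: int
    strand: str
    protein_id: str
    is_codh: bool = False
    pseudo: bool = False

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gene {self.protein_id}: start > end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.protein_id}: bad strand {self.strand!r}")


@dataclass
class Directon:
    replicon_id: str
    strand: str
    genes: list[GeneRecord]
    codh_protein_ids: list[str]

    @property
    def protein_ids(self) -> list[str]:
        return [g.protein_id for g in self.genes]


@dataclass
class ContextLocus:
    """Curated genomic context of one CODH gene."""

    codh_protein_id: str
    genome_id: str
    directon_protein_ids: list[str]
    expansion_protein_ids: list[str]
    cogs: frozenset[str]
    group_label: Optional[str] = None
    phylum: Optional[str] = None
    family: Optional[str] = None

    @property
    def member_protein_ids(self) -> list[str]:
        return self.directon_protein_ids + self.expansion_protein_ids


def genes_from_dataframe(df: pd.DataFrame,
                         codh_ids: Optional[set[str]] = None,
                         drop_pseudo: bool = True) -> dict[str, list[GeneRecord]]:
    """Group a gene table into per-replicon, start-sorted GeneRecord lists.

    Pseudogene rows are dropped before directon construction.  When
    *codh_ids* is given it overrides any ``is_codh`` column.
    """
    out: dict[str, list[GeneRecord]] = {}
    df = df.sort_values(["replicon_id", "start"], kind="mergesort")
    for rep, sub in df.groupby("replicon_id", sort=True):
        genes = []
        for i, (_, r) in enumerate(sub.iterrows()):
            pseudo = bool(r.get("pseudo", False))
            if drop_pseudo and pseudo:
                continue
            is_codh = (
                r.protein_id in codh_ids if codh_ids is not None
                else bool(r.get("is_codh", False))
            )
            genes.append(GeneRecord(
                genome_id=str(r.genome_id), replicon_id=str(rep),
                index=len(genes), start=int(r.start), end=int(r.end),
                strand=str(r.strand), protein_id=str(r.protein_id),
                is_codh=is_codh, pseudo=pseudo,
            ))
        out[str(rep)] = genes
    return out


def intergenic_gap(left: GeneRecord, right: GeneRecord) -> int:
    """Base pairs strictly between two genes; overlaps count as 0."""
    return max(right.start - left.end - 1, 0)


def build_directon(genes: Sequence[GeneRecord], codh_index: int,
                   max_gap_bp: int = DEFAULT_MAX_GAP_BP,
                   max_side_genes: int = DEFAULT_MAX_SIDE_GENES) -> Directon:
    """The CODH-anchored directon of ``genes[codh_index]``.

    Extends in both directions while the next gene is on the same strand,
    the intergenic gap is <= *max_gap_bp*, and at most *max_side_genes* have
    been added on that side.
    """
    if not 0 <= codh_index < len(genes):
        raise IndexError("codh_index out of range")
    anchor = genes[codh_index]
    lo = codh_index
    while lo > 0 and codh_index - lo < max_side_genes:
        nxt = genes[lo - 1]
        if nxt.strand != anchor.strand or \
                intergenic_gap(nxt, genes[lo]) > max_gap_bp:
            break
        lo -= 1
    hi = codh_index
    while hi < len(genes) - 1 and hi - codh_index < max_side_genes:
        nxt = genes[hi + 1]
        if nxt.strand != anchor.strand or \
                intergenic_gap(genes[hi], nxt) > max_gap_bp:
            break
        hi += 1
    members = list(genes[lo : hi + 1])
    return Directon(
        replicon_id=anchor.replicon_id,
        strand=anchor.strand,
        genes=members,
        codh_protein_ids=[g.protein_id for g in members if g.is_codh],
    )


def build_all_directons(genes_by_replicon: Mapping[str, Sequence[GeneRecord]],
                        max_gap_bp: int = DEFAULT_MAX_GAP_BP,
                        max_side_genes: int = DEFAULT_MAX_SIDE_GENES,
                        ) -> dict[str, Directon]:
    """One directon per CODH gene, keyed by the CODH protein id."""
    out: dict[str, Directon] = {}
    for genes in genes_by_replicon.values():
        for i, g in enumerate(genes):
            if g.is_codh:
                out[g.protein_id] = build_directon(
                    genes, i, max_gap_bp, max_side_genes
                )
    return out


def expand_context(directon: Directon, genes: Sequence[GeneRecord],
                   enriched_cogs: set[str],
                   annotations: Mapping[str, set[str]]) -> list[GeneRecord]:
    """Flanking genes added to the directon by the enriched-COG rule.

    On each side, the gene immediately flanking the current context is added
    when it carries at least one enriched COG — regardless of strand or
    distance — and expansion stops at the first flank without one (or at the
    replicon end).  Returns the added genes in replicon order.
    """
    by_index = {g.index: g for g in genes}
    lo = directon.genes[0].index
    hi = directon.genes[-1].index
    added: list[GeneRecord] = []
    i = lo - 1
    while i in by_index and annotations.get(by_index[i].protein_id, set()) & enriched_cogs:
        added.insert(0, by_index[i])
        i -= 1
    i = hi + 1
    while i in by_index and annotations.get(by_index[i].protein_id, set()) & enriched_cogs:
        added.append(by_index[i])
        i += 1
    return added


def build_context_loci(
    genes_by_replicon: Mapping[str, Sequence[GeneRecord]],
    directons: Mapping[str, Directon],
    enriched_cogs: set[str],
    annotations: Mapping[str, set[str]],
    group_labels: Optional[Mapping[str, str]] = None,
    taxonomy: Optional[Mapping[str, tuple[str, str]]] = None,
) -> list[ContextLocus]:
    """One :class:`ContextLocus` per CODH gene.

    Feature content: COGs carried by any member gene, the CODH protein's
    structural-group label, and the genome's (phylum, family) labels.
    """
    loci = []
    for codh_pid, directon in sorted(directons.items()):
        genes = genes_by_replicon[directon.replicon_id]
        expansion = expand_context(directon, genes, enriched_cogs, annotations)
        member_ids = directon.protein_ids + [g.protein_id for g in expansion]
        cogs = frozenset().union(
            *(frozenset(annotations.get(pid, set())) for pid in member_ids)
        ) if member_ids else frozenset()
        genome = directon.genes[0].genome_id
        phylum, family = (taxonomy or {}).get(genome, (None, None))
        loci.append(ContextLocus(
            codh_protein_id=codh_pid,
            genome_id=genome,
            directon_protein_ids=directon.protein_ids,
            expansion_protein_ids=[g.protein_id for g in expansion],
            cogs=cogs,
            group_label=(group_labels or {}).get(codh_pid),
            phylum=phylum,
            family=family,
        ))
    return loci
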