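"""End-to-end pipeline: curate -> classify -> context -> enrich -> network.

All stage thresholds default to the printed rule constants of the analysis
(bit score 200, length 550, trim threshold 0.9, directon gap 300 bp, 15 genes
per side, p and FDR 0.05, Simpson 0.4, COG locus floor 25).  A fixed config
plus seed yields byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import io as nio
from .align import assign_clade, map_anchor_positions
from .anchors import load_anchors
from .classify import build_signature, assign_structural_group
from .context import build_all_directons, build_context_loci, genes_from_dataframe
from .curation import (
    deduplicate_proteins, filter_complete_sequences, filter_hits,
    select_representative_genomes,
)
from .enrichment import (
    build_feature_matrix, build_network, edges_to_dataframe, edges_to_graph,
    enrichment_to_dataframe, find_enriched_cogs, EXCLUDED_COGS,
)
from .records import GenomeMetadata, HitRecord

logger = logging.getLogger("nicodh")


class InputError(Exception):
    """Missing or unreadable input (CLI exit code 2)."""


class InvariantError(Exception):
    """Internal contract violation (CLI exit code 3)."""


@dataclass
class PipelineConfig:
    fasta: str = ""
    gff3: str = ""
    annotations: str = ""
    metadata: str = ""
    anchors: str = ""
    hits: Optional[str] = None
    out_dir: str = "nicodh_out"
    min_bit_score: float = 200.0
    min_length: int = 550
    gap_threshold: float = 0.9
    max_gap_bp: int = 300
    max_side_genes: int = 15
    alpha: float = 0.05
    fdr: float = 0.05
    tau: float = 0.4
    min_cog_loci: int = 25
    ambiguity_delta: float = 5.0
    max_evalue: float = 1e-6
    seed: int = 0

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self),
                                             sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise InputError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _require(path: str, what: str) -> Path:
    if not path:
        raise InputError(f"no {what} path configured")
    p = Path(path)
    if not p.exists():
        raise InputError(f"{what} file not found: {p}")
    return p


def classify_sequences(proteins, anchors, ambiguity_delta: float = 5.0):
    """Map and classify a list of ProteinRecords against the anchors.

    Returns ``(assignments, position_maps)`` keyed by protein id, where each
    assignment carries clade, ambiguity flag, structural group and signature.
    """
    assignments = {}
    maps = {}
    anchor_by_clade = {a.clade: a for a in anchors}
    for rec in proteins:
        call = assign_clade(rec.sequence, anchors, ambiguity_delta=ambiguity_delta)
        anchor = anchor_by_clade[call.clade]
        pmap = map_anchor_positions(rec.id, rec.sequence, anchor)
        maps[rec.id] = pmap
        sig = build_signature(rec.sequence, pmap, anchor)
        assignments[rec.id] = assign_structural_group(
            call.clade, sig, protein_id=rec.id, clade_ambiguous=call.ambiguous
        )
    return assignments, maps


def assignments_to_dataframe(assignments) -> pd.DataFrame:
    rows = []
    for pid in sorted(assignments):
        a = assignments[pid]
        s = a.signature
        rows.append({
            "protein_id": pid, "clade": a.clade, "ambiguous": a.clade_ambiguous,
            "group_label": a.group_label, "d_type": s.d_type or "-",
            "c_cluster": "".join(x if len(x) == 1 else "." for x in s.c_cluster),
            "acid_base": "".join(x if len(x) == 1 else "." for x in s.acid_base),
            "b_complete": s.b_complete,
            "e_complete": s.e_complete, "f_complete": s.f_complete,
            "nterm_cys": s.nterm_cys_count, "cterm_cys": s.cterm_cys_count,
            "nterm_his_rich": s.nterm_his_rich, "cterm_his_rich": s.cterm_his_rich,
            "c_insertion_cys4": s.c_insertion_cys4,
            "extra_ef_cys4": s.extra_ef_cys4_count, "fusion": s.fusion,
        })
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages and write stage outputs plus a run report."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": dataclasses.asdict(config), "counts": {}}
    counts = report["counts"]

    anchors_path = Path(config.anchors) if config.anchors else None
    if anchors_path is None or not anchors_path.exists():
        raise InputError(
            "anchor profiles not found; generate them with `nicodh simulate` "
            "or supply --anchors"
        )
    anchors = load_anchors(anchors_path)

    proteins = nio.read_fasta(_require(config.fasta, "FASTA"))
    if not proteins:
        raise InputError(f"no sequences in FASTA input {config.fasta}")
    counts["proteins_input"] = len(proteins)

    # --- curation ----------------------------------------------------------
    if config.hits:
        hits_df = nio.read_hits(_require(config.hits, "hit table"))
        hits = [HitRecord(str(r.subject_id), float(r.bit_score),
                          int(r.subject_length))
                for r in hits_df.itertuples()]
        retained_ids = set(filter_hits(hits, config.min_bit_score,
                                       config.min_length))
        proteins = [p for p in proteins if p.id in retained_ids]
    else:
        proteins = [p for p in proteins if len(p.sequence) >= config.min_length]
    proteins = deduplicate_proteins(proteins)
    counts["proteins_curated"] = len(proteins)
    if not proteins:
        raise InputError("no sequences survived curation")

    # --- classification ----------------------------------------------------
    assignments, maps = classify_sequences(proteins, anchors,
                                           config.ambiguity_delta)
    complete_ids = set(filter_complete_sequences(maps))
    assignments = {pid: a for pid, a in assignments.items()
                   if pid in complete_ids}
    counts["proteins_complete"] = len(assignments)
    cls_df = assignments_to_dataframe(assignments)
    cls_df.to_csv(out / "classifications.tsv", sep="\t", index=False)
    group_tally = (cls_df["group_label"].value_counts().sort_index().to_dict()
                   if not cls_df.empty else {})
    clade_tally = (cls_df["clade"].value_counts().sort_index().to_dict()
                   if not cls_df.empty else {})
    report["group_tally"] = {k: int(v) for k, v in group_tally.items()}
    report["clade_tally"] = {k: int(v) for k, v in clade_tally.items()}

    # --- genome selection & gene tables ------------------------------------
    genes_df = nio.read_gff3(_require(config.gff3, "GFF3"))
    meta_df = nio.read_metadata(_require(config.metadata, "metadata"))
    codh_ids = set(assignments)
    codh_by_genome: dict[str, set[str]] = {}
    for _, g in genes_df.iterrows():
        if g.protein_id in codh_ids:
            codh_by_genome.setdefault(g.genome_id, set()).add(g.protein_id)
    metadata = [
        GenomeMetadata(
            genome_id=r.genome_id, species_key=r.species_key,
            assembly_category=r.assembly_category,
            assembly_level=r.assembly_level,
            phylum=getattr(r, "phylum", ""), family=getattr(r, "family", ""),
            codh_protein_ids=frozenset(codh_by_genome.get(r.genome_id, ())),
        )
        for r in meta_df.itertuples()
        if r.genome_id in codh_by_genome
    ]
    selected_genomes = set(select_representative_genomes(metadata))
    counts["genomes_codh"] = len(codh_by_genome)
    counts["genomes_selected"] = len(selected_genomes)
    genes_df = genes_df[genes_df["genome_id"].isin(selected_genomes)]
    counts["genes_total"] = len(genes_df)

    # --- genomic context ----------------------------------------------------
    genes_by_rep = genes_from_dataframe(genes_df, codh_ids=codh_ids)
    directons = build_all_directons(genes_by_rep, config.max_gap_bp,
                                    config.max_side_genes)
    counts["codh_genes"] = len(directons)
    ann_df = nio.read_annotations(_require(config.annotations, "annotation table"),
                                  max_evalue=config.max_evalue)
    annotations: dict[str, set[str]] = {}
    for r in ann_df.itertuples():
        annotations.setdefault(str(r.protein_id), set()).add(str(r.cog))

    taxonomy = {
        r.genome_id: (getattr(r, "phylum", ""), getattr(r, "family", ""))
        for r in meta_df.itertuples()
    }
    group_labels = {pid: a.group_label for pid, a in assignments.items()}

    # enrichment is computed on the raw directons, then contexts are expanded
    base_loci = build_context_loci(genes_by_rep, directons, set(), annotations,
                                   group_labels, taxonomy)
    enriched, results = find_enriched_cogs(
        base_loci, genes_by_rep, annotations,
        alpha=config.alpha, fdr=config.fdr,
    )
    counts["cogs_tested"] = len(results)
    counts["cogs_enriched"] = len(enriched)
    enrichment_to_dataframe(results).to_csv(out / "enrichment.tsv", sep="\t",
                                            index=False)

    loci = build_context_loci(genes_by_rep, directons, enriched, annotations,
                              group_labels, taxonomy)
    counts["context_loci"] = len(loci)
    pd.DataFrame([
        {"codh_protein_id": l.codh_protein_id, "genome_id": l.genome_id,
         "group_label": l.group_label,
         "directon_members": ",".join(l.directon_protein_ids),
         "expansion_members": ",".join(l.expansion_protein_ids),
         "cogs": ",".join(sorted(l.cogs))}
        for l in loci
    ]).to_csv(out / "context_loci.tsv", sep="\t", index=False)

    # --- network ------------------------------------------------------------
    matrix = build_feature_matrix(loci, enriched)
    edges = build_network(matrix, tau=config.tau,
                          min_cog_loci=config.min_cog_loci)
    counts["network_edges"] = len(edges)
    edges_to_dataframe(edges).to_csv(out / "edges.tsv", sep="\t", index=False)
    import networkx as nx

    nx.write_graphml(edges_to_graph(edges), out / "network.graphml")
    matrix.to_csv(out / "feature_matrix.tsv", sep="\t")

    (out / "report.json").write_text(json.dumps(report, indent=1,
                                                sort_keys=True) + "\n")
    logger.info("pipeline finished: %s", counts)
    return report
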