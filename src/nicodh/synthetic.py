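"""Synthetic test-bed generator with planted, fully known ground truth.

Real Ni-CODH surveys start from database-scale inputs; this module builds
miniature stand-ins with the same statistical structure so every downstream
stage can be validated against a known answer:

* protein sequences realizing the cluster-motif signature of any of the 24
  structural groups on a per-clade random scaffold,
* one reference anchor per clade (A–G) carrying the canonical signature,
* genomes whose CODH genes sit inside same-strand directons with controlled
  intergenic gaps, with designated COGs co-occurring with the CODH directon at
  a chosen probability over a uniform annotation background.

Scaffold residues are drawn i.i.d. from a background alphabet that excludes
Cys and His, so planted Cys/His motifs are unambiguous by construction.  All
randomness is keyed by explicit seeds; identical seeds give identical output.
"""

from __future__ import annotations

import json
import hashlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import io as nio
from .anchors import (
    ACID_BASE, B_CLUSTER, C_CLUSTER, CLADES, CORE_END, CORE_START,
    D_REGION_SPAN, E_CLUSTER, F_CLUSTER, SCAFFOLD_LENGTH, AnchorProfile,
)
from .classify import STRUCTURAL_GROUPS
from .records import ProteinRecord

#: scaffold alphabet: 18 residues, no Cys, no His
BACKGROUND_AA = "ADEFGIKLMNPQRSTVWY"

#: group realized on each clade's reference anchor
_CANONICAL_GROUP = {"A": "A-1", "B": "B-4", "C": "C-2", "D": "D-4",
                    "E": "E-1", "F": "F-1", "G": "G-1"}

_D_PATTERNS = {
    "I": "C..CC",
    "II": "C.......CC",  # spacer 7 (valid range 7-13)
    "III": "C..C.....C",
}

_NTERM_CYS_POS = 15
_NTERM_HIS_POS = 8
_CTERM_HIS_POS = 620
_EF_INSERT_POS = (210, 255)
_C_INSERT_POS = 400


@dataclass(frozen=True)
class GroupTemplate:
    """A structural group's planted-motif recipe on a clade scaffold.

    ``motif_spec`` is an ordered list of ``(region_name, pattern, start)``
    entries; in a pattern, a letter is planted at that position and ``.``
    keeps the scaffold residue (motif spacer).  ``scaffold`` is the clade
    background sequence the motifs are planted into.
    """

    group_label: str
    clade: str
    scaffold_length: int
    motif_spec: tuple[tuple[str, str, int], ...]
    scaffold: str

    def __post_init__(self) -> None:
        for name, pattern, start in self.motif_spec:
            if start < 1 or start + len(pattern) - 1 > self.scaffold_length:
                raise ValueError(
                    f"motif {name!r} at {start} outside [1, {self.scaffold_length}]"
                )
        if len(self.scaffold) != self.scaffold_length:
            raise ValueError("scaffold length mismatch")

    def protected_positions(self) -> set[int]:
        """1-based positions carrying planted (non-spacer) motif residues."""
        prot = set()
        for _name, pattern, start in self.motif_spec:
            for off, ch in enumerate(pattern):
                if ch != ".":
                    prot.add(start + off)
        return prot

    def realize(self) -> str:
        seq = list(self.scaffold)
        for _name, pattern, start in self.motif_spec:
            for off, ch in enumerate(pattern):
                if ch != ".":
                    seq[start - 1 + off] = ch
        return "".join(seq)


def _clade_scaffold(clade: str, seed: int) -> str:
    rng = np.random.default_rng([int(seed) % (2**31), 17, CLADES.index(clade)])
    idx = rng.integers(0, len(BACKGROUND_AA), size=SCAFFOLD_LENGTH)
    return "".join(BACKGROUND_AA[i] for i in idx)


def _group_motif_spec(label: str) -> tuple[tuple[str, str, int], ...]:
    row = STRUCTURAL_GROUPS[label]
    spec: list[tuple[str, str, int]] = []
    if row["d"] is not None:
        spec.append(("d_cluster", _D_PATTERNS[row["d"]], D_REGION_SPAN[0]))
    for i, pos in enumerate(B_CLUSTER, 1):
        spec.append((f"b{i}", "C", pos))
    for name, res, pos in zip(
        ("c_his", "c_cys1", "c_cys2", "c_cys3", "c_cys4", "c_cys5"),
        row["c"], C_CLUSTER,
    ):
        spec.append((name, res, pos))
    spec.append(("ab_his", row["ab"][0], ACID_BASE[0]))
    spec.append(("ab_lys", row["ab"][1], ACID_BASE[1]))
    ef = row["ef"]
    if ef in ("complete", "e_only"):
        for i, pos in enumerate(E_CLUSTER, 1):
            spec.append((f"e{i}", "C", pos))
        f_positions = F_CLUSTER if ef == "complete" else F_CLUSTER[:3]
        for i, pos in enumerate(f_positions, 1):
            spec.append((f"f{i}", "C", pos))
    for motif in row["motifs"]:
        if motif == "nterm_cys2":
            spec.append(("nterm_cys", "CC", _NTERM_CYS_POS))
        elif motif == "nterm_cys3":
            spec.append(("nterm_cys", "CCC", _NTERM_CYS_POS))
        elif motif == "nterm_his_rich":
            spec.append(("nterm_his_rich", "HAHAHAH", _NTERM_HIS_POS))
        elif motif == "cterm_his_rich":
            spec.append(("cterm_his_rich", "HAHAHAH", _CTERM_HIS_POS))
        elif motif == "ef_cys4x2":
            spec.append(("ef_insert_1", "CCCC", _EF_INSERT_POS[0]))
            spec.append(("ef_insert_2", "CCCC", _EF_INSERT_POS[1]))
        elif motif == "c_insert_cys4":
            spec.append(("c_insert", "CCCC", _C_INSERT_POS))
        elif motif == "d_single_cys":
            spec.append(("d_single_cys", "C", D_REGION_SPAN[0]))
        else:  # pragma: no cover - guarded by STRUCTURAL_GROUPS contents
            raise ValueError(f"unknown accessory motif {motif!r}")
    return tuple(spec)


def build_group_templates(seed: int) -> dict[str, GroupTemplate]:
    """One :class:`GroupTemplate` per structural group, on clade scaffolds."""
    templates = {}
    for label, row in STRUCTURAL_GROUPS.items():
        clade = row["clade"]
        templates[label] = GroupTemplate(
            group_label=label,
            clade=clade,
            scaffold_length=SCAFFOLD_LENGTH,
            motif_spec=_group_motif_spec(label),
            scaffold=_clade_scaffold(clade, seed),
        )
    return templates


def generate_reference_anchors(seed: int) -> list[AnchorProfile]:
    """One anchor per clade A–G, realizing the clade's canonical group.

    Deterministic in *seed*; only the clade A anchor carries E-/F-cluster
    positions (the Cdh-type extra cubanes).
    """
    templates = build_group_templates(seed)
    anchors = []
    for clade in CLADES:
        tmpl = templates[_CANONICAL_GROUP[clade]]
        has_ef = clade == "A"
        anchors.append(AnchorProfile(
            clade=clade,
            sequence=tmpl.realize(),
            d_region_span=D_REGION_SPAN,
            b_cluster=B_CLUSTER,
            c_cluster=C_CLUSTER,
            acid_base=ACID_BASE,
            core_start=CORE_START,
            core_end=CORE_END,
            e_cluster=E_CLUSTER if has_ef else None,
            f_cluster=F_CLUSTER if has_ef else None,
        ))
    return anchors


def generate_protein_for_group(
    template: GroupTemplate,
    mutation_rate: float = 0.0,
    protect_motifs: bool = True,
    seed: int = 0,
    protein_id: Optional[str] = None,
    genome_id: Optional[str] = None,
) -> ProteinRecord:
    """Realize a group template, optionally with background substitutions.

    Substitutions are applied per site at *mutation_rate*, drawn from the
    Cys/His-free background alphabet; with *protect_motifs* on, planted motif
    residues are never touched.
    """
    if not 0.0 <= mutation_rate <= 1.0:
        raise ValueError("mutation_rate must be in [0, 1]")
    seq = list(template.realize())
    if mutation_rate > 0:
        rng = np.random.default_rng([int(seed) % (2**31), 23])
        protected = template.protected_positions() if protect_motifs else set()
        for pos in range(1, len(seq) + 1):
            if pos in protected:
                continue
            if rng.random() < mutation_rate:
                choices = [a for a in BACKGROUND_AA if a != seq[pos - 1]]
                seq[pos - 1] = choices[rng.integers(0, len(choices))]
    pid = protein_id or f"SYN_{template.group_label}"
    return ProteinRecord(id=pid, sequence="".join(seq), genome_id=genome_id)


# ---------------------------------------------------------------------------
# genome-context scenarios
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ContextScenario:
    """Parameters of a planted genome-context experiment.

    Each genome gets one replicon of ``genes_per_replicon`` CDS rows with
    bounded-uniform gene lengths and intergenic gaps; one CODH gene per genome
    (group labels cycled from ``codh_groups``).  For each ``(cog, p)`` in
    ``enriched_cogs``, a gene inside the CODH directon is annotated with that
    COG with probability ``p`` per genome; ``background_cogs`` are sprinkled
    uniformly at their genome-wide frequency.  Strand flips between adjacent
    genes break directons at ``strand_flip_rate``, except inside a protected
    window of ``protected_flank`` genes either side of the CODH gene, which is
    kept same-strand so a directon to plant into always exists.
    """

    n_genomes: int = 50
    genes_per_replicon: int = 60
    codh_groups: tuple[str, ...] = ("F-1", "C-2", "A-1")
    enriched_cogs: tuple[tuple[str, float], ...] = (
        ("COG0437", 0.9), ("COG1614", 0.9), ("COG3640", 0.9),
    )
    background_cogs: tuple[tuple[str, float], ...] = tuple(
        (f"COG9{i:03d}", 0.02) for i in range(200)
    )
    intergenic_gap_law: tuple[int, int] = (50, 200)
    gene_length_law: tuple[int, int] = (300, 1500)
    strand_flip_rate: float = 0.2
    protected_flank: int = 3
    mutation_rate: float = 0.05
    protect_motifs: bool = True
    max_gap_bp: int = 300
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genomes < 1 or self.genes_per_replicon < 1:
            raise ValueError("counts must be positive")
        for cog, p in self.enriched_cogs:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"co-occurrence probability for {cog} not in [0,1]")
        for cog, p in self.background_cogs:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"background frequency for {cog} not in [0,1]")
        if not 0.0 <= self.strand_flip_rate <= 1.0:
            raise ValueError("strand_flip_rate must be in [0,1]")
        if self.intergenic_gap_law[0] > self.intergenic_gap_law[1] \
                or self.intergenic_gap_law[0] < 0:
            raise ValueError("invalid intergenic gap law")
        for g in self.codh_groups:
            if g not in STRUCTURAL_GROUPS:
                raise ValueError(f"unknown structural group {g!r}")
        if 1 + 2 * self.protected_flank > self.genes_per_replicon:
            raise ValueError("planted genes exceed genes_per_replicon")


@dataclass
class FixtureBundle:
    """In-memory result of :func:`generate_context_genomes`."""

    genes: pd.DataFrame
    annotations: pd.DataFrame
    metadata: pd.DataFrame
    proteins: list[ProteinRecord]
    hits: pd.DataFrame
    manifest: dict


def _directon_members(genes: list[dict], codh_i: int, max_gap: int,
                      max_side: int = 15) -> list[int]:
    """Indices of the CODH directon under the same-strand / gap rule."""
    strand = genes[codh_i]["strand"]
    members = [codh_i]
    i = codh_i
    while i > 0 and codh_i - (i - 1) <= max_side:
        gap = genes[i]["start"] - genes[i - 1]["end"] - 1
        if genes[i - 1]["strand"] != strand or max(gap, 0) > max_gap:
            break
        i -= 1
        members.insert(0, i)
    i = codh_i
    while i < len(genes) - 1 and (i + 1) - codh_i <= max_side:
        gap = genes[i + 1]["start"] - genes[i]["end"] - 1
        if genes[i + 1]["strand"] != strand or max(gap, 0) > max_gap:
            break
        i += 1
        members.append(i)
    return members


_PHYLA = ("Firmicutes", "Proteobacteria", "Euryarchaeota", "Chloroflexi",
          "Nitrospirae")
_FAMILIES = tuple(f"Family{i:02d}" for i in range(1, 9))


def generate_context_genomes(scenario: ContextScenario) -> FixtureBundle:
    """Generate gene tables, annotations, metadata, proteins and ground truth."""
    templates = build_group_templates(scenario.seed)
    rng = np.random.default_rng([scenario.seed % (2**31), 31])
    gene_rows, ann_rows, meta_rows, hit_rows = [], [], [], []
    proteins: list[ProteinRecord] = []
    manifest: dict = {
        "seed": scenario.seed,
        "codh_genes": {},
        "enriched_cogs": {cog: {"p": p, "planted_in": []}
                          for cog, p in scenario.enriched_cogs},
        "directon_members": {},
    }

    for gi in range(scenario.n_genomes):
        genome = f"SYN_g{gi + 1:03d}"
        replicon = f"{genome}_r1"
        n = scenario.genes_per_replicon
        codh_i = n // 2
        group = scenario.codh_groups[gi % len(scenario.codh_groups)]

        # coordinates
        glo, ghi = scenario.gene_length_law
        dlo, dhi = scenario.intergenic_gap_law
        lengths = rng.integers(glo, ghi + 1, size=n)
        gaps = rng.integers(dlo, dhi + 1, size=n)
        # strands: flip chain, then force the protected window to one strand
        strands = ["+"]
        for _ in range(1, n):
            flip = rng.random() < scenario.strand_flip_rate
            strands.append(
                ("-" if strands[-1] == "+" else "+") if flip else strands[-1]
            )
        w0 = codh_i - scenario.protected_flank
        w1 = codh_i + scenario.protected_flank
        for i in range(w0, w1 + 1):
            strands[i] = strands[codh_i]

        genes = []
        pos = 1
        for i in range(n):
            start, end = pos, pos + int(lengths[i]) - 1
            pid = f"{genome}_{i + 1:04d}"
            genes.append({
                "genome_id": genome, "replicon_id": replicon, "index": i,
                "start": start, "end": end, "strand": strands[i],
                "protein_id": pid, "is_codh": i == codh_i, "pseudo": False,
            })
            pos = end + int(gaps[i]) + 1
        gene_rows.extend(genes)

        codh_pid = genes[codh_i]["protein_id"]
        manifest["codh_genes"][codh_pid] = {"genome": genome, "group": group}
        members = _directon_members(genes, codh_i, scenario.max_gap_bp)
        manifest["directon_members"][codh_pid] = [
            genes[i]["protein_id"] for i in members
        ]

        # annotations: CODH marker COG, planted enriched COGs, background
        ann_rows.append({"protein_id": codh_pid, "cog": "COG1151",
                         "evalue": 1e-30})
        window = [i for i in range(w0, w1 + 1) if i != codh_i]
        for cog, p in scenario.enriched_cogs:
            if rng.random() < p:
                target = window[rng.integers(0, len(window))]
                ann_rows.append({"protein_id": genes[target]["protein_id"],
                                 "cog": cog, "evalue": 1e-20})
                manifest["enriched_cogs"][cog]["planted_in"].append(codh_pid)
        for cog, freq in scenario.background_cogs:
            mask = rng.random(n) < freq
            for i in np.nonzero(mask)[0]:
                ann_rows.append({"protein_id": genes[int(i)]["protein_id"],
                                 "cog": cog, "evalue": 1e-10})

        # proteins: full-length CODH realization + short background proteins
        codh_protein = generate_protein_for_group(
            templates[group], scenario.mutation_rate, scenario.protect_motifs,
            seed=(scenario.seed * 1009 + gi) % (2**31),
            protein_id=codh_pid, genome_id=genome,
        )
        proteins.append(codh_protein)
        hit_rows.append({"subject_id": codh_pid,
                         "bit_score": float(500 + rng.integers(0, 200)),
                         "subject_length": len(codh_protein.sequence)})
        for i in range(n):
            if i == codh_i:
                continue
            ln = int(rng.integers(80, 121))
            idx = rng.integers(0, len(BACKGROUND_AA), size=ln)
            proteins.append(ProteinRecord(
                id=genes[i]["protein_id"],
                sequence="".join(BACKGROUND_AA[k] for k in idx),
                genome_id=genome,
            ))
            hit_rows.append({"subject_id": genes[i]["protein_id"],
                             "bit_score": float(rng.integers(30, 150)),
                             "subject_length": ln})

        meta_rows.append({
            "genome_id": genome,
            "species_key": f"Species_{genome}",
            "assembly_category": "na",
            "assembly_level": "contig",
            "phylum": _PHYLA[int(rng.integers(0, len(_PHYLA)))],
            "family": _FAMILIES[int(rng.integers(0, len(_FAMILIES)))],
        })

    return FixtureBundle(
        genes=pd.DataFrame(gene_rows, columns=nio.GENE_COLUMNS),
        annotations=pd.DataFrame(ann_rows, columns=["protein_id", "cog", "evalue"]),
        metadata=pd.DataFrame(meta_rows),
        proteins=proteins,
        hits=pd.DataFrame(hit_rows, columns=["subject_id", "bit_score",
                                             "subject_length"]),
        manifest=manifest,
    )


def write_fixture_bundle(bundle: FixtureBundle, directory: str | Path,
                         anchors: Optional[Sequence[AnchorProfile]] = None) -> dict:
    """Write the bundle as FASTA/GFF3/TSV files plus a ground-truth manifest.

    Returns the manifest (also written as ``manifest.json``).  File contents
    are deterministic for a given bundle.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    nio.write_fasta(bundle.proteins, directory / "proteins.faa")
    nio.write_gff3(bundle.genes, directory / "genes.gff3")
    nio.write_annotations(bundle.annotations, directory / "annotations.tsv")
    nio.write_metadata(bundle.metadata, directory / "metadata.tsv")
    nio.write_hits(bundle.hits, directory / "hits.tsv")
    if anchors is not None:
        from .anchors import save_anchors

        save_anchors(anchors, directory / "anchors.json")
    manifest = dict(bundle.manifest)
    (directory / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True) + "\n"
    )
    return manifest


def load_fixture_bundle(directory: str | Path) -> FixtureBundle:
    """Re-read a written bundle into the in-memory form."""
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    return FixtureBundle(
        genes=nio.read_gff3(directory / "genes.gff3"),
        annotations=nio.read_annotations(directory / "annotations.tsv"),
        metadata=nio.read_metadata(directory / "metadata.tsv"),
        proteins=nio.read_fasta(directory / "proteins.faa"),
        hits=nio.read_hits(directory / "hits.tsv"),
        manifest=manifest,
    )
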