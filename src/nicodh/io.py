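"""Readers and writers for the pipeline's on-disk formats.

FASTA goes through Biopython; the tabular formats (GFF3 CDS rows, annotation
and metadata TSVs, BLAST-style hit tables) are flat and are handled with
pandas.  GFF3 coordinates are 1-based inclusive; gene rows carry a
``protein_id`` attribute and an optional ``pseudo`` flag.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .records import ProteinRecord

GENE_COLUMNS = [
    "genome_id", "replicon_id", "index", "start", "end",
    "strand", "protein_id", "is_codh", "pseudo",
]


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        genome = None
        m = re.search(r"genome=(\S+)", rec.description)
        if m:
            genome = m.group(1)
        records.append(ProteinRecord(id=rec.id, sequence=str(rec.seq),
                                     genome_id=genome,
                                     description=rec.description))
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    seqs = []
    for r in records:
        desc = f"genome={r.genome_id}" if r.genome_id else ""
        seqs.append(SeqRecord(Seq(r.sequence), id=r.id, description=desc))
    SeqIO.write(seqs, str(path), "fasta")


def write_gff3(genes: pd.DataFrame, path: str | Path) -> None:
    """Write gene rows as GFF3 CDS features.

    ``genes`` must carry the columns in :data:`GENE_COLUMNS`.
    """
    lines = ["##gff-version 3"]
    for _, g in genes.iterrows():
        attrs = (
            f"ID={g.protein_id};protein_id={g.protein_id};"
            f"genome_id={g.genome_id};is_codh={str(bool(g.is_codh)).lower()};"
            f"pseudo={str(bool(g.pseudo)).lower()}"
        )
        lines.append("\t".join([
            str(g.replicon_id), "nicodh", "CDS", str(int(g.start)),
            str(int(g.end)), ".", str(g.strand), "0", attrs,
        ]))
    Path(path).write_text("\n".join(lines) + "\n")


def _attr(attrs: str, key: str) -> str | None:
    m = re.search(rf"(?:^|;){key}=([^;]+)", attrs)
    return m.group(1) if m else None


def read_gff3(path: str | Path) -> pd.DataFrame:
    """Parse GFF3 CDS rows into the canonical gene table.

    Rows of other feature types are ignored; missing attributes default to
    ``is_codh=False``, ``pseudo=False`` and ``genome_id=<replicon>``.
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9 or parts[2] != "CDS":
                continue
            seqid, _src, _type, start, end, _score, strand, _phase, attrs = parts
            pid = _attr(attrs, "protein_id") or _attr(attrs, "ID")
            rows.append({
                "genome_id": _attr(attrs, "genome_id") or seqid,
                "replicon_id": seqid,
                "start": int(start),
                "end": int(end),
                "strand": strand,
                "protein_id": pid,
                "is_codh": (_attr(attrs, "is_codh") or "false") == "true",
                "pseudo": (_attr(attrs, "pseudo") or "false") == "true",
            })
    df = pd.DataFrame(rows)
    if df.empty:
        return pd.DataFrame(columns=GENE_COLUMNS)
    df = df.sort_values(["replicon_id", "start"], kind="mergesort")
    df["index"] = df.groupby("replicon_id").cumcount()
    return df[GENE_COLUMNS].reset_index(drop=True)


def read_annotations(path: str | Path, max_evalue: float = 1e-6) -> pd.DataFrame:
    """Read the protein -> COG annotation TSV.

    When an ``evalue`` column is present, rows at or above *max_evalue* are
    dropped (the annotation search's significance cut); otherwise annotations
    are taken as given.
    """
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str, "cog": str})
    if "evalue" in df.columns and max_evalue is not None:
        df = df[df["evalue"] < max_evalue]
    return df.reset_index(drop=True)


def write_annotations(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_metadata(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str)


def write_metadata(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_hits(path: str | Path,
              subject_col: str = "subject_id",
              score_col: str = "bit_score",
              length_col: str = "subject_length") -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    return df.rename(columns={subject_col: "subject_id", score_col: "bit_score",
                              length_col: "subject_length"})


def write_hits(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)
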