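"""Protein sequence records and their on-disk formats (FASTA + annotation TSV)."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .digestion import CANONICAL_AA

ANNOTATION_COLUMNS = ["accession", "gene_symbol", "keywords"]


@dataclass(frozen=True)
class ProteinRecord:
    """One sequence-database entry.

    ``species`` distinguishes the cultured-cell species ("cell") from the
    serum-supplement species ("serum"); only cell-species proteins are
    quantified, the serum database exists to identify shared tryptic
    peptides that must be excluded as potential serum contaminants.
    """

    accession: str
    gene_symbol: str
    species: str  # "cell" | "serum"
    sequence: str
    keywords: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.accession}: empty sequence")
        bad = set(self.sequence) - CANONICAL_AA
        if bad:
            raise ValueError(f"{self.accession}: non-canonical residues {sorted(bad)}")
        if self.species not in ("cell", "serum"):
            raise ValueError(f"{self.accession}: unknown species {self.species!r}")


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.accession, description=r.gene_symbol)
        for r in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")


def read_fasta(path: str | Path, species: str) -> list[ProteinRecord]:
    """Read a FASTA database; the description's first word is the gene symbol."""
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        desc = rec.description.split(maxsplit=1)
        gene = desc[1].split()[0] if len(desc) > 1 else rec.id
        out.append(ProteinRecord(rec.id, gene, species, str(rec.seq)))
    return out


def sequences_by_accession(records: Iterable[ProteinRecord]) -> dict[str, str]:
    out: dict[str, str] = {}
    for r in records:
        if r.accession in out:
            raise ValueError(f"duplicate accession {r.accession}")
        out[r.accession] = r.sequence
    return out


def write_annotation_table(records: Iterable[ProteinRecord], path: str | Path) -> None:
    """Annotation TSV: accession, gene_symbol, semicolon-separated keywords."""
    df = pd.DataFrame(
        [
            {
                "accession": r.accession,
                "gene_symbol": r.gene_symbol,
                "keywords": ";".join(sorted(r.keywords)),
            }
            for r in records
        ],
        columns=ANNOTATION_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def read_annotation_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna({"keywords": ""})
    missing = set(ANNOTATION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"annotation table missing columns: {sorted(missing)}")
    return df
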