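"""Readers and writers for the pipeline's on-disk formats.

Sequences travel as FASTA (via Biopython); tables as TSV with a one-line
header. Sample metadata lives in its own TSV keyed by ``sample_id``.
Integer counts round-trip bit-exact.
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .types import AbundanceTable, SampleMeta, TaxonRecord

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_abundance_table",
    "write_abundance_table",
    "read_sample_metadata",
    "write_sample_metadata",
]


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    """Load a FASTA file as an ordered {seq_id: uppercase sequence} mapping."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path: str | os.PathLike) -> None:
    records = (SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items())
    SeqIO.write(records, str(path), "fasta")


def write_sample_metadata(samples: Iterable[SampleMeta], path: str | os.PathLike) -> None:
    rows = [
        {
            "sample_id": s.sample_id,
            "group": s.group,
            "block": s.block if s.block is not None else "",
            "total_reads": s.total_reads,
            "total_bases": s.total_bases,
        }
        for s in samples
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_sample_metadata(path: str | os.PathLike) -> list[SampleMeta]:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "group": str, "block": str})
    out = []
    for row in df.itertuples(index=False):
        block = getattr(row, "block", "")
        if pd.isna(block) or block == "":
            block = None
        out.append(
            SampleMeta(
                sample_id=str(row.sample_id),
                group="" if pd.isna(row.group) else str(row.group),
                block=block,
                total_reads=int(getattr(row, "total_reads", 0) or 0),
                total_bases=int(getattr(row, "total_bases", 0) or 0),
            )
        )
    return out


def write_abundance_table(table: AbundanceTable, path: str | os.PathLike) -> None:
    """Write the sample x taxon matrix as TSV (samples on rows)."""
    table.values.rename_axis("sample_id").to_csv(path, sep="\t")


def read_abundance_table(
    path: str | os.PathLike,
    value_kind: str = "read_count",
    samples: list[SampleMeta] | None = None,
    taxa: list[TaxonRecord] | None = None,
) -> AbundanceTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return AbundanceTable(df, value_kind, samples or [], taxa or [])
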