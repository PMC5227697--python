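"""File-format adapters: FASTQ/FASTA via Biopython, sheets via pandas."""

from __future__ import annotations

from pathlib import Path
from typing import Iterator

import pandas as pd
from Bio import SeqIO

from .qc import SequenceRead
from .simulate import ReferenceRecord


def read_fastq(path: str | Path, mate: int = 1, sample_id: str = "") -> list[SequenceRead]:
    reads = []
    for rec in SeqIO.parse(str(path), "fastq"):
        reads.append(
            SequenceRead(
                rec.id,
                str(rec.seq),
                rec.letter_annotations["phred_quality"],
                mate,
                sample_id,
            )
        )
    return reads


def read_fastq_pairs(
    r1_path: str | Path, r2_path: str | Path, sample_id: str = ""
) -> Iterator[tuple[SequenceRead, SequenceRead]]:
    r1 = read_fastq(r1_path, 1, sample_id)
    r2 = read_fastq(r2_path, 2, sample_id)
    if len(r1) != len(r2):
        raise ValueError(f"unequal mate counts for sample {sample_id!r}")
    return zip(r1, r2)


def read_reference_fasta(path: str | Path) -> list[ReferenceRecord]:
    """Parse the structured reference header dialect.

    ``>ACC|family|genus|species|habitat|local:{0,1}|fishery:{0,1}``
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        fields = rec.description.split("|")
        if len(fields) != 7:
            raise ValueError(f"malformed reference header: {rec.description!r}")
        acc, family, genus, species, habitat, local, fishery = fields
        records.append(
            ReferenceRecord(
                accession=acc,
                family=family,
                genus=genus,
                species=species,
                habitat=habitat,
                local=local.split(":")[1] == "1",
                fishery=fishery.split(":")[1] == "1",
                sequence=str(rec.seq),
            )
        )
    return records


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    sheet = pd.read_csv(path, dtype={"sample_id": str, "station_id": str, "layer": str})
    required = {"sample_id", "station_id", "layer", "replicate", "is_negative", "x_m", "y_m"}
    missing = required - set(sheet.columns)
    if missing:
        raise ValueError(f"sample sheet misses columns: {sorted(missing)}")
    sheet["station_id"] = sheet["station_id"].fillna("")
    sheet["layer"] = sheet["layer"].fillna("")
    return sheet


def write_inserts_fasta(inserts: list[str], sample_id: str, path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, seq in enumerate(inserts):
            fh.write(f">{sample_id}.insert.{i + 1}\n{seq}\n")


def read_inserts_fasta(path: str | Path) -> list[str]:
    return [str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")]
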