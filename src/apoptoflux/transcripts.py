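"""Transcript models: 5'UTR / CDS / 3'UTR structure and sequence handling.

A :class:`TranscriptModel` is the coordinate frame for every positional
operation in the package: read assignment, region RPKM, metagene alignment
and uORF scanning all express positions as 0-based offsets on the spliced
transcript, with the CDS occupying ``[utr5_len, utr5_len + cds_len)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "TranscriptModel",
    "load_transcript_table",
    "save_transcript_table",
    "load_fasta",
    "save_fasta",
]


@dataclass(frozen=True)
class TranscriptModel:
    """Region structure of a canonical spliced transcript.

    Parameters
    ----------
    transcript_id :
        Unique identifier.
    utr5_len, cds_len, utr3_len :
        Region lengths in nucleotides. ``cds_len`` must be a positive
        multiple of 3 (it includes the stop codon).
    sequence :
        Optional spliced sequence over ACGTN whose length equals the sum
        of the three region lengths.
    """

    transcript_id: str
    utr5_len: int
    cds_len: int
    utr3_len: int
    sequence: str | None = None

    def __post_init__(self) -> None:
        if self.utr5_len < 0 or self.utr3_len < 0:
            raise ValueError(f"{self.transcript_id}: UTR lengths must be >= 0")
        if self.cds_len < 3 or self.cds_len % 3 != 0:
            raise ValueError(
                f"{self.transcript_id}: cds_len must be a positive multiple of 3, "
                f"got {self.cds_len}"
            )
        if self.sequence is not None and len(self.sequence) != self.length:
            raise ValueError(
                f"{self.transcript_id}: sequence length {len(self.sequence)} != "
                f"region sum {self.length}"
            )

    @property
    def length(self) -> int:
        """Total spliced transcript length in nt."""
        return self.utr5_len + self.cds_len + self.utr3_len

    @property
    def cds_start(self) -> int:
        """0-based offset of the first CDS nucleotide (the A of AUG)."""
        return self.utr5_len

    @property
    def cds_end(self) -> int:
        """0-based half-open end of the CDS (first nt of the 3'UTR)."""
        return self.utr5_len + self.cds_len

    def region_of(self, position: int) -> str:
        """Return 'utr5', 'cds' or 'utr3' for a 0-based transcript position."""
        if not 0 <= position < self.length:
            raise ValueError(
                f"position {position} outside transcript {self.transcript_id} "
                f"of length {self.length}"
            )
        if position < self.cds_start:
            return "utr5"
        if position < self.cds_end:
            return "cds"
        return "utr3"


def load_transcript_table(path: str | Path) -> dict[str, TranscriptModel]:
    """Read a transcripts.tsv (id, utr5_len, cds_len, utr3_len) into models."""
    df = pd.read_csv(path, sep="\t", dtype={"id": str})
    required = {"id", "utr5_len", "cds_len", "utr3_len"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"transcript table missing columns: {sorted(missing)}")
    return {
        row.id: TranscriptModel(row.id, int(row.utr5_len), int(row.cds_len), int(row.utr3_len))
        for row in df.itertuples()
    }


def save_transcript_table(models: Iterable[TranscriptModel], path: str | Path) -> None:
    """Write models as transcripts.tsv with a fixed header."""
    rows = [
        {"id": m.transcript_id, "utr5_len": m.utr5_len, "cds_len": m.cds_len,
         "utr3_len": m.utr3_len}
        for m in models
    ]
    pd.DataFrame(rows, columns=["id", "utr5_len", "cds_len", "utr3_len"]).to_csv(
        path, sep="\t", index=False
    )


def load_fasta(path: str | Path) -> dict[str, str]:
    """Read transcript sequences keyed by record id."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def save_fasta(sequences: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=tid, description="") for tid, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def attach_sequences(
    models: dict[str, TranscriptModel], sequences: dict[str, str]
) -> dict[str, TranscriptModel]:
    """Return models with sequences attached where available."""
    out: dict[str, TranscriptModel] = {}
    for tid, m in models.items():
        seq = sequences.get(tid)
        out[tid] = TranscriptModel(m.transcript_id, m.utr5_len, m.cds_len, m.utr3_len, seq)
    return out
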