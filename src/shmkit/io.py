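"""Readers and writers for the plain-text formats used across shmkit.

FASTA/FASTQ go through Biopython; tabular data through pandas.  The
repertoire table reader accepts AIRR-rearrangement-style column names as
aliases and rejects (with a logged count) records carrying N bases or
length mismatches, mirroring the upstream exclusion of records with
unknown bases or indels.
"""

from __future__ import annotations

import gzip
import logging
from typing import Iterable, Optional, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import DataError
from .motifs import NucleotideSequence
from .mutpe import SequencedRead
from .repertoire import AnnotatedSequenceRecord

logger = logging.getLogger("shmkit")

_AIRR_ALIASES = {
    "sequence_id": "record_id",
    "germline_alignment": "germline",
    "sequence_alignment": "observed",
}


def _open(path, mode="rt"):
    if str(path).endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path) -> list[NucleotideSequence]:
    with _open(path) as handle:
        return [
            NucleotideSequence(str(rec.seq).upper(), rec.id)
            for rec in SeqIO.parse(handle, "fasta")
        ]


def write_fasta(sequences: Iterable[NucleotideSequence], path) -> None:
    records = [
        SeqRecord(Seq(s.bases), id=s.name or f"seq{i}", description="")
        for i, s in enumerate(sequences)
    ]
    with _open(path, "wt") as handle:
        SeqIO.write(records, handle, "fasta")


def read_fastq(path, mate: int = 1) -> list[SequencedRead]:
    """Phred+33 FASTQ into SequencedRead objects."""
    with _open(path) as handle:
        return [
            SequencedRead(
                rec.id,
                str(rec.seq).upper(),
                tuple(rec.letter_annotations["phred_quality"]),
                mate,
            )
            for rec in SeqIO.parse(handle, "fastq")
        ]


def write_fastq(reads: Iterable[SequencedRead], path) -> None:
    with _open(path, "wt") as handle:
        for read in reads:
            rec = SeqRecord(Seq(read.bases), id=read.read_id, description="")
            rec.letter_annotations["phred_quality"] = list(read.qualities)
            SeqIO.write([rec], handle, "fastq")


def _parse_regions(cell: str) -> tuple[tuple[str, int, int], ...]:
    """Parse a region string like 'FWR1:1-78,CDR1:79-114'."""
    if not cell or pd.isna(cell):
        return ()
    out = []
    for part in str(cell).split(","):
        label, span = part.split(":")
        start, end = span.split("-")
        out.append((label.strip(), int(start), int(end)))
    return tuple(out)


def format_regions(region_map: Sequence[tuple[str, int, int]]) -> str:
    return ",".join(f"{label}:{start}-{end}" for label, start, end in region_map)


def read_repertoire_tsv(path) -> list[AnnotatedSequenceRecord]:
    """Load a repertoire table; invalid records are dropped and counted.

    Expected columns: record_id, germline, observed, regions (optional);
    AIRR-style aliases (sequence_id, germline_alignment,
    sequence_alignment) are accepted.
    """
    table = pd.read_csv(path, sep="\t", dtype=str)
    table = table.rename(columns=_AIRR_ALIASES)
    for column in ("record_id", "germline", "observed"):
        if column not in table.columns:
            raise DataError(f"repertoire table missing column {column!r}")
    records = []
    rejected = 0
    for row in table.itertuples(index=False):
        regions = _parse_regions(getattr(row, "regions", ""))
        try:
            records.append(
                AnnotatedSequenceRecord(
                    row.record_id,
                    row.germline.upper(),
                    row.observed.upper(),
                    regions,
                )
            )
        except DataError:
            rejected += 1
    if rejected:
        logger.warning("rejected %d records with N bases or length mismatches", rejected)
    return records


def write_repertoire_tsv(records: Iterable[AnnotatedSequenceRecord], path) -> None:
    rows = [
        {
            "record_id": r.record_id,
            "germline": r.germline,
            "observed": r.observed,
            "regions": format_regions(r.region_map),
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
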