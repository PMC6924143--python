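"""Reading and writing ODN sequence files and activity tables.

FASTA handles sequences alone; the activity table is a delimited text file
(TSV or CSV, header required) with columns ``id``, ``sequence`` and
``activity`` carrying the reporter-assay score alongside each sequence.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Sequence

import pandas as pd
from Bio import SeqIO

from .records import OdnRecord, validate_sequence

REQUIRED_COLUMNS = ("id", "sequence", "activity")


def read_fasta(path: str | Path) -> list[OdnRecord]:
    """Read ODNs from a FASTA file, validating and uppercasing sequences."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records = [
        OdnRecord(id=entry.id, sequence=validate_sequence(str(entry.seq), entry.id))
        for entry in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Sequence[OdnRecord], path: str | Path) -> None:
    """Write records as single-line-sequence FASTA."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n{rec.sequence}\n")


def _sniff_sep(path: Path) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def read_activity_table(path: str | Path) -> list[OdnRecord]:
    """Read an id/sequence/activity table (TSV or CSV with a header row)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=_sniff_sep(path), dtype={"id": str, "sequence": str})
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    dupes = df["id"][df["id"].duplicated()].tolist()
    if dupes:
        raise ValueError(f"{path}: duplicate id(s) {sorted(set(dupes))}")
    records: list[OdnRecord] = []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            activity = float(row.activity)
        except (TypeError, ValueError):
            raise ValueError(
                f"{path}: row {i + 2} (id {row.id!r}): "
                f"non-numeric activity {row.activity!r}"
            ) from None
        if activity != activity:  # NaN, e.g. pandas-parsed "NA"
            raise ValueError(f"{path}: row {i + 2} (id {row.id!r}): non-numeric activity")
        records.append(
            OdnRecord(id=str(row.id), sequence=validate_sequence(row.sequence, row.id),
                      activity=activity)
        )
    return records


def write_activity_table(records: Sequence[OdnRecord], path: str | Path, sep: str = "\t") -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=sep, lineterminator="\n")
        writer.writerow(REQUIRED_COLUMNS)
        for rec in records:
            if rec.activity is None:
                raise ValueError(f"record {rec.id!r} has no activity value")
            writer.writerow([rec.id, rec.sequence, f"{rec.activity:.6g}"])
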