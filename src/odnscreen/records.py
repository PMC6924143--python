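"""Core record types for oligodeoxynucleotide (ODN) datasets.

An ODN here is a short single-stranded DNA sequence (typically a 24-mer)
with an optional reporter-assay activity score and an optional binary
activity class. The activity score is the optical-density readout of an
NF-kB/AP-1 reporter assay, a unitless value from 0.0 (no receptor
activation) up to about 1.14 in the calibration data this package models.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

HIGH = "high"
LOW = "low"

_VALID_BASES = frozenset("ACGT")


class SequenceAlphabetError(ValueError):
    """Raised when a sequence contains characters outside {A, C, G, T}."""


@dataclass(frozen=True)
class OdnRecord:
    """One oligonucleotide: identifier, sequence, optional activity and label."""

    id: str
    sequence: str
    activity: float | None = None
    label: str | None = None

    def __post_init__(self) -> None:
        if self.label is not None and self.label not in (HIGH, LOW):
            raise ValueError(f"label must be '{HIGH}' or '{LOW}', got {self.label!r}")

    def with_label(self, label: str) -> "OdnRecord":
        return replace(self, label=label)


@dataclass(frozen=True)
class LabelPolicy:
    """Activity threshold separating high- from low-activity ODNs.

    Scores at or above ``cutoff`` are labelled high; the default 0.4 is the
    reporter-assay cutoff used throughout this package.
    """

    cutoff: float = 0.4

    def __post_init__(self) -> None:
        if not self.cutoff > 0:
            raise ValueError(f"cutoff must be > 0, got {self.cutoff}")

    def label_for(self, activity: float) -> str:
        return HIGH if activity >= self.cutoff else LOW


def validate_sequence(sequence: str, record_id: str = "<unnamed>") -> str:
    """Uppercase ``sequence`` and reject anything outside {A, C, G, T}.

    Lowercase input is normalised; ambiguity codes, gaps or other characters
    are hard errors at ingestion time (descriptor counting has its own,
    laxer rule for already-ingested text).
    """
    seq = sequence.upper()
    if not seq:
        raise SequenceAlphabetError(f"record {record_id!r}: empty sequence")
    bad = sorted(set(seq) - _VALID_BASES)
    if bad:
        raise SequenceAlphabetError(
            f"record {record_id!r}: invalid character(s) {', '.join(map(repr, bad))} "
            "(alphabet is A/C/G/T)"
        )
    return seq


def assign_labels(
    records: Sequence[OdnRecord], policy: LabelPolicy | None = None
) -> list[OdnRecord]:
    """Label every record high/low from its activity score.

    Every record must carry an activity value; the returned list preserves
    order and always partitions into the two classes.
    """
    policy = policy or LabelPolicy()
    out: list[OdnRecord] = []
    for rec in records:
        if rec.activity is None:
            raise ValueError(f"record {rec.id!r} has no activity value; cannot label")
        out.append(rec.with_label(policy.label_for(rec.activity)))
    return out


def split_by_label(records: Iterable[OdnRecord]) -> tuple[list[OdnRecord], list[OdnRecord]]:
    """Partition labelled records into (high, low) preserving order."""
    high: list[OdnRecord] = []
    low: list[OdnRecord] = []
    for rec in records:
        if rec.label == HIGH:
            high.append(rec)
        elif rec.label == LOW:
            low.append(rec)
        else:
            raise ValueError(f"record {rec.id!r} is unlabelled")
    return high, low
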