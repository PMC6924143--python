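"""Positional motif fingerprints.

A sequence is chopped into every substring of length 2..6 together with its
1-based start position; each (motif, start) pair is one *token*. Tokens
whose per-ODN occurrence rate differs by at least a threshold (default 10
percentage points) between the high- and low-activity groups form the
fingerprint dictionary, and each ODN is then encoded as a binary vector of
token presence. The same fingerprints drive Tanimoto-similarity
deduplication of near-identical ODNs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np

from .records import OdnRecord

MIN_MOTIF_LEN = 2
MAX_MOTIF_LEN = 6


class MotifToken(NamedTuple):
    """A motif string anchored at a 1-based start position."""

    motif: str
    start: int

    @property
    def name(self) -> str:
        """Column-name form, e.g. CG1 or GT18."""
        return f"{self.motif}{self.start}"


def enumerate_motifs(
    sequence: str,
    min_len: int = MIN_MOTIF_LEN,
    max_len: int = MAX_MOTIF_LEN,
) -> set[MotifToken]:
    """All (substring, 1-based start) tokens of length ``min_len``..``max_len``.

    Overlapping occurrences are all reported; a sequence shorter than
    ``min_len`` yields the empty set.
    """
    L = len(sequence)
    return {
        MotifToken(sequence[i : i + k], i + 1)
        for k in range(min_len, max_len + 1)
        for i in range(L - k + 1)
    }


def _contains_token(sequence: str, token: MotifToken) -> bool:
    i = token.start - 1
    return sequence[i : i + len(token.motif)] == token.motif


def occurrence_rates(
    records: Sequence[OdnRecord], tokens: Iterable[MotifToken] | None = None
) -> dict[MotifToken, float]:
    """Fraction of ODNs in ``records`` containing each token.

    An ODN counts once per token regardless of how it matches. With
    ``tokens=None`` every token observed anywhere in the group is rated.
    """
    if not records:
        raise ValueError("occurrence_rates: empty group")
    per_record = [enumerate_motifs(r.sequence) for r in records]
    if tokens is None:
        tokens = set().union(*per_record)
    n = len(records)
    return {t: sum(t in toks for toks in per_record) / n for t in tokens}


@dataclass
class FingerprintDictionary:
    """Ordered token dictionary with the group occurrence rates behind it."""

    tokens: list[MotifToken]
    rate_high: dict[MotifToken, float]
    rate_low: dict[MotifToken, float]
    threshold: float = 0.10

    def __len__(self) -> int:
        return len(self.tokens)

    @property
    def names(self) -> list[str]:
        return [t.name for t in self.tokens]

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("motif\tstart\trate_high\trate_low\n")
            for t in self.tokens:
                fh.write(
                    f"{t.motif}\t{t.start}\t{self.rate_high[t]:.6g}\t{self.rate_low[t]:.6g}\n"
                )

    @classmethod
    def from_tsv(cls, path: str | Path, threshold: float = 0.10) -> "FingerprintDictionary":
        tokens: list[MotifToken] = []
        rate_high: dict[MotifToken, float] = {}
        rate_low: dict[MotifToken, float] = {}
        with open(path) as fh:
            next(fh)
            for line in fh:
                motif, start, rh, rl = line.rstrip("\n").split("\t")
                t = MotifToken(motif, int(start))
                tokens.append(t)
                rate_high[t] = float(rh)
                rate_low[t] = float(rl)
        return cls(tokens, rate_high, rate_low, threshold)


def build_dictionary(
    high: Sequence[OdnRecord],
    low: Sequence[OdnRecord],
    threshold: float = 0.10,
) -> FingerprintDictionary:
    """Tokens whose occurrence rate differs by ≥ ``threshold`` between groups.

    Tokens are ordered by descending |rate_high − rate_low|, ties broken
    lexicographically on (motif, start), so the dictionary is deterministic.
    """
    if not high or not low:
        raise ValueError("build_dictionary: both groups must be non-empty")
    all_tokens = set()
    per_high = [enumerate_motifs(r.sequence) for r in high]
    per_low = [enumerate_motifs(r.sequence) for r in low]
    all_tokens.update(*per_high, *per_low)
    nh, nl = len(high), len(low)
    rate_high = {t: sum(t in s for s in per_high) / nh for t in all_tokens}
    rate_low = {t: sum(t in s for s in per_low) / nl for t in all_tokens}
    # small slack so a difference of exactly the threshold survives floating
    # point (the rule is inclusive: "at least" the threshold)
    kept = [t for t in all_tokens if abs(rate_high[t] - rate_low[t]) >= threshold - 1e-12]
    kept.sort(key=lambda t: (-abs(rate_high[t] - rate_low[t]), t.motif, t.start))
    return FingerprintDictionary(
        tokens=kept,
        rate_high={t: rate_high[t] for t in kept},
        rate_low={t: rate_low[t] for t in kept},
        threshold=threshold,
    )


def encode_fingerprint(sequence: str, dictionary: FingerprintDictionary) -> np.ndarray:
    """Binary vector: bit i is 1 iff dictionary token i matches the sequence
    at exactly its stored start position."""
    return np.array(
        [1 if _contains_token(sequence, t) else 0 for t in dictionary.tokens],
        dtype=np.uint8,
    )


def tanimoto(a: np.ndarray, b: np.ndarray) -> float:
    """Tanimoto/Jaccard similarity of two equal-length binary vectors.

    Two all-zero vectors are defined as identical (similarity 1).
    """
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"fingerprint length mismatch: {a.shape} vs {b.shape}")
    union = int(np.logical_or(a, b).sum())
    if union == 0:
        return 1.0
    return int(np.logical_and(a, b).sum()) / union


def dedup_by_similarity(
    records: Sequence[OdnRecord],
    dictionary: FingerprintDictionary,
    cutoff: float = 0.85,
) -> tuple[list[OdnRecord], list[OdnRecord]]:
    """Greedy leader clustering on fingerprint Tanimoto similarity.

    Records are scanned in input order; one is removed iff its similarity to
    an already-kept record is ≥ ``cutoff``. Returns (kept, removed) with
    kept ∪ removed == input.
    """
    kept: list[OdnRecord] = []
    kept_fps: list[np.ndarray] = []
    removed: list[OdnRecord] = []
    for rec in records:
        fp = encode_fingerprint(rec.sequence, dictionary)
        if any(tanimoto(fp, leader) >= cutoff for leader in kept_fps):
            removed.append(rec)
        else:
            kept.append(rec)
            kept_fps.append(fp)
    return kept, removed
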