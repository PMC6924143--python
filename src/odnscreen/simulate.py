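"""Synthetic ODN generation with planted motif effects.

``random_odns`` draws uniform random sequences (the screening-library
model: every position i.i.d. over A/C/G/T). ``simulate_activity`` assigns
each sequence a reporter-style activity score

    activity = clip(baseline + Σ_{motif present} effect(motif) + N(0, σ)),

with position-free motif containment, so the generator's ground truth —
which motifs raise or lower activity, and by how much — is known exactly
and every downstream component (labelling, dictionary building, the
ensemble, motif statistics) can be tested against it.

Defaults emulate the calibration data this package models: 24-mers, a low
baseline of 0.18, effects {GGC: +0.35, CCCG: +0.30, TCT: −0.10} (so the
high/low medians sit near 0.53/0.18 around the 0.4 class cutoff, with the
low class in the majority), Gaussian noise with σ = 0.05, and scores
clipped to [0, 1.14].
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .records import OdnRecord

BASES = "ACGT"

DEFAULT_MOTIF_EFFECTS: dict[str, float] = {"GGC": 0.35, "CCCG": 0.30, "TCT": -0.10}


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic dataset."""

    n: int = 400
    length: int = 24
    seed: int = 0
    baseline: float = 0.18
    motif_effects: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MOTIF_EFFECTS)
    )
    noise_sd: float = 0.05
    clip: tuple[float, float] = (0.0, 1.14)

    def __post_init__(self) -> None:
        if self.length < 6:
            raise ValueError("length must be ≥ 6")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be ≥ 0")
        if not self.clip[0] <= self.clip[1]:
            raise ValueError("clip bounds must be ordered")


def random_odns(
    n: int, length: int = 24, seed: int = 0, id_prefix: str = "ODN"
) -> list[OdnRecord]:
    """n i.i.d.-uniform random DNA sequences of the given length."""
    if n < 0:
        raise ValueError("n must be ≥ 0")
    rng = np.random.default_rng(seed)
    width = max(5, len(str(n)))
    draws = rng.integers(0, 4, size=(n, length))
    return [
        OdnRecord(
            id=f"{id_prefix}{i + 1:0{width}d}",
            sequence="".join(BASES[b] for b in row),
        )
        for i, row in enumerate(draws)
    ]


def simulate_activity(
    records: Sequence[OdnRecord], config: SimulationConfig
) -> list[OdnRecord]:
    """Assign each record an activity score under the planted-effect model.

    Deterministic for a given config; motif presence is position-free
    containment, each planted motif contributing its effect once.
    """
    rng = np.random.default_rng(config.seed)
    noise = rng.normal(0.0, config.noise_sd, size=len(records)) if config.noise_sd > 0 \
        else np.zeros(len(records))
    lo, hi = config.clip
    out: list[OdnRecord] = []
    for rec, eps in zip(records, noise):
        activity = config.baseline + eps
        for motif, effect in config.motif_effects.items():
            if motif in rec.sequence:
                activity += effect
        out.append(replace(rec, activity=float(np.clip(activity, lo, hi))))
    return out


def simulate_dataset(config: SimulationConfig) -> list[OdnRecord]:
    """Generate ``config.n`` random ODNs and score them under the planted
    model; sequence and noise draws use independent streams derived from
    ``config.seed``."""
    records = random_odns(config.n, length=config.length, seed=config.seed)
    return simulate_activity(records, config)


def motif_enrichment(
    selection: Sequence[OdnRecord],
    pool: Sequence[OdnRecord],
    motifs: Sequence[str],
) -> dict[str, float]:
    """Containment-rate enrichment of each motif in ``selection`` relative
    to ``pool``, plus their mean under key ``'mean'``.

    Enrichment for a motif is (fraction of the selection containing it) /
    (fraction of the pool containing it). Note the per-motif value is
    bounded above by 1 / pool-fraction, so common motifs can never show
    large fold-enrichments; the mean across planted motifs is the summary
    used by the package's end-to-end checks.
    """
    if not selection or not pool:
        raise ValueError("selection and pool must be non-empty")
    out: dict[str, float] = {}
    vals = []
    for m in motifs:
        pool_frac = sum(m in r.sequence for r in pool) / len(pool)
        sel_frac = sum(m in r.sequence for r in selection) / len(selection)
        if pool_frac == 0:
            raise ValueError(f"motif {m!r} absent from the pool; enrichment undefined")
        out[m] = sel_frac / pool_frac
        vals.append(out[m])
    out["mean"] = float(np.mean(vals))
    return out
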