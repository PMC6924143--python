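"""Seeded experimental design: repeated down-sampling, stratified train/test
splits and stratified k-fold partitions.

Class imbalance is handled by *repeated random down-sampling*: in each of
``n_repeats`` repetitions the majority class is subsampled without
replacement to the minority size, the balanced set is split 80/20 per
class, and the training part is partitioned into stratified folds for
cross-validated tuning. Every repetition derives its own seed from the
master seed (seed + repeat index), so any single repetition is reproducible
in isolation and the whole plan serializes to a deterministic text file.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .records import HIGH, LOW, OdnRecord


def _ids_by_class(records: Sequence[OdnRecord]) -> tuple[list[str], list[str]]:
    high = [r.id for r in records if r.label == HIGH]
    low = [r.id for r in records if r.label == LOW]
    unlabelled = [r.id for r in records if r.label not in (HIGH, LOW)]
    if unlabelled:
        raise ValueError(f"unlabelled record(s): {unlabelled[:5]}")
    return high, low


def down_sample(
    high: Sequence[str], low: Sequence[str], seed: int
) -> tuple[list[str], list[str]]:
    """Balance the two classes by subsampling the majority without
    replacement to the minority size. Returns (high_kept, low_kept), each in
    original order."""
    if not high or not low:
        raise ValueError("down_sample: both classes must be non-empty")
    rng = np.random.default_rng(seed)
    n = min(len(high), len(low))

    def pick(ids: Sequence[str]) -> list[str]:
        if len(ids) == n:
            return list(ids)
        chosen = rng.choice(len(ids), size=n, replace=False)
        keep = set(chosen.tolist())
        return [x for i, x in enumerate(ids) if i in keep]

    return pick(high), pick(low)


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def stratified_split(
    high: Sequence[str],
    low: Sequence[str],
    train_fraction: float = 0.8,
    seed: int = 0,
) -> tuple[list[str], list[str]]:
    """Per-class random split; round(train_fraction · n) to nearest goes to
    train (117 × 0.8 = 93.6 → 94), the remainder to test."""
    rng = np.random.default_rng(seed)
    train: list[str] = []
    test: list[str] = []
    for ids in (high, low):
        if len(ids) < 2:
            raise ValueError("stratified_split: each class needs ≥ 2 members")
        n_train = _round_half_up(train_fraction * len(ids))
        perm = rng.permutation(len(ids))
        chosen = set(perm[:n_train].tolist())
        train += [x for i, x in enumerate(ids) if i in chosen]
        test += [x for i, x in enumerate(ids) if i not in chosen]
    return train, test


def kfold(
    ids: Sequence[str], labels: Sequence[str], k: int, seed: int = 0
) -> dict[str, int]:
    """Stratified k-fold assignment id → fold (0-based).

    Within each class, members are shuffled and dealt as evenly as possible;
    per-class remainders start at rotating fold offsets so that overall fold
    sizes also differ by at most one.
    """
    if len(ids) != len(labels):
        raise ValueError("ids and labels length mismatch")
    rng = np.random.default_rng(seed)
    by_class: dict[str, list[str]] = {}
    for i, lab in zip(ids, labels):
        by_class.setdefault(lab, []).append(i)
    for members in by_class.values():
        if k > len(members):
            raise ValueError(f"k={k} exceeds a class size of {len(members)}")
    assignment: dict[str, int] = {}
    offset = 0
    for lab in sorted(by_class):
        members = list(by_class[lab])
        rng.shuffle(members)
        base, rem = divmod(len(members), k)
        sizes = [base + (1 if (f - offset) % k < rem else 0) for f in range(k)]
        pos = 0
        for f, size in enumerate(sizes):
            for m in members[pos : pos + size]:
                assignment[m] = f
            pos += size
        offset = (offset + rem) % k
    return assignment


@dataclass
class RepeatPlan:
    """One down-sampling repetition: its seed, memberships and folds."""

    index: int
    seed: int
    train_ids: list[str]
    test_ids: list[str]
    folds: dict[str, int]  # train id -> fold


@dataclass
class SplitPlan:
    """The full deterministic audit trail of an experiment."""

    seed: int
    n_repeats: int
    train_fraction: float
    k: int
    repeats: list[RepeatPlan] = field(default_factory=list)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(
                f"#seed={self.seed}\tn_repeats={self.n_repeats}"
                f"\ttrain_fraction={self.train_fraction}\tk={self.k}\n"
            )
            fh.write("repeat\tseed\trole\tid\tfold\n")
            for rep in self.repeats:
                for i in rep.train_ids:
                    fh.write(f"{rep.index}\t{rep.seed}\ttrain\t{i}\t{rep.folds[i]}\n")
                for i in rep.test_ids:
                    fh.write(f"{rep.index}\t{rep.seed}\ttest\t{i}\t-\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SplitPlan":
        with open(path) as fh:
            header = fh.readline().lstrip("#").rstrip("\n")
            meta = dict(kv.split("=") for kv in header.split("\t"))
            plan = cls(
                seed=int(meta["seed"]),
                n_repeats=int(meta["n_repeats"]),
                train_fraction=float(meta["train_fraction"]),
                k=int(meta["k"]),
            )
            fh.readline()  # column header
            reps: dict[int, RepeatPlan] = {}
            for line in fh:
                idx_s, seed_s, role, rid, fold_s = line.rstrip("\n").split("\t")
                idx = int(idx_s)
                rep = reps.setdefault(
                    idx, RepeatPlan(index=idx, seed=int(seed_s), train_ids=[], test_ids=[], folds={})
                )
                if role == "train":
                    rep.train_ids.append(rid)
                    rep.folds[rid] = int(fold_s)
                else:
                    rep.test_ids.append(rid)
        plan.repeats = [reps[i] for i in sorted(reps)]
        return plan


def build_plan(
    records: Sequence[OdnRecord],
    n_repeats: int = 20,
    train_fraction: float = 0.8,
    k: int = 20,
    seed: int = 0,
) -> SplitPlan:
    """n_repeats independent down-sample → split → k-fold instances, with
    repetition i seeded by ``seed + i``."""
    high, low = _ids_by_class(records)
    labels = {r.id: r.label for r in records}
    plan = SplitPlan(seed=seed, n_repeats=n_repeats, train_fraction=train_fraction, k=k)
    for i in range(n_repeats):
        rep_seed = seed + i
        h_kept, l_kept = down_sample(high, low, seed=rep_seed)
        train, test = stratified_split(h_kept, l_kept, train_fraction, seed=rep_seed)
        folds = kfold(train, [labels[t] for t in train], k=k, seed=rep_seed)
        plan.repeats.append(
            RepeatPlan(index=i, seed=rep_seed, train_ids=train, test_ids=test, folds=folds)
        )
    return plan
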