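"""Feature filtering and normalisation.

Four fitted-on-train-only steps: near-zero-variance removal (sample SD
below a threshold), removal of exact linear combinations, greedy
correlation filtering of numeric features, and centering/scaling. A
``FeaturePipeline`` bundles them with the conventions used throughout this
package: binary fingerprint columns get the variance and linear-combination
filters only and stay 0/1; numeric columns additionally get the correlation
filter and are standardised.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

_LINCOMB_TOL = 1e-8


def nzv_filter(
    matrix: pd.DataFrame, sd_threshold: float = 0.3
) -> tuple[pd.DataFrame, list[str]]:
    """Drop columns whose sample standard deviation (n−1) is < threshold."""
    if len(matrix) < 2:
        raise ValueError("nzv_filter needs at least 2 rows")
    sds = matrix.std(ddof=1)
    dropped = [c for c in matrix.columns if sds[c] < sd_threshold]
    return matrix.drop(columns=dropped), dropped


def lincomb_filter(matrix: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Drop later-ordered columns that are linear combinations of earlier
    ones (an implicit intercept column is always in the span).

    Uses incremental Gram–Schmidt with re-orthogonalisation; a column whose
    residual norm falls below ``1e-8`` relative to its own norm is dropped.
    """
    n = len(matrix)
    basis = [np.full(n, 1.0 / np.sqrt(n))] if n else []
    dropped: list[str] = []
    for col in matrix.columns:
        x = matrix[col].to_numpy(dtype=float)
        r = x.copy()
        for q in basis:
            r -= (q @ r) * q
        for q in basis:  # second pass for numerical stability
            r -= (q @ r) * q
        norm = np.linalg.norm(r)
        if norm <= _LINCOMB_TOL * max(1.0, np.linalg.norm(x)):
            dropped.append(col)
        else:
            basis.append(r / norm)
    return matrix.drop(columns=dropped), dropped


def correlation_filter(
    matrix: pd.DataFrame, cutoff: float = 0.85
) -> tuple[pd.DataFrame, list[str]]:
    """Greedy removal of highly correlated columns.

    While some pair has |Pearson r| strictly above ``cutoff``, remove from
    the worst pair the member with the larger mean |r| against all
    remaining columns (ties: the later column in input order goes).
    """
    if len(matrix) < 3:
        raise ValueError("correlation_filter needs at least 3 rows")
    if (matrix.std(ddof=1) == 0).any():
        zero = [c for c in matrix.columns if matrix[c].std(ddof=1) == 0]
        raise ValueError(f"zero-variance column(s) {zero}; run nzv_filter first")
    cols = list(matrix.columns)
    corr = matrix.corr().abs()
    dropped: list[str] = []
    while len(cols) > 1:
        sub = corr.loc[cols, cols].to_numpy(copy=True)
        np.fill_diagonal(sub, 0.0)
        i, j = np.unravel_index(np.argmax(sub), sub.shape)
        if sub[i, j] <= cutoff:
            break
        mean_i = sub[i].sum() / (len(cols) - 1)
        mean_j = sub[j].sum() / (len(cols) - 1)
        if mean_i > mean_j:
            victim = cols[i]
        elif mean_j > mean_i:
            victim = cols[j]
        else:  # tie: later in column order
            victim = cols[max(i, j)]
        dropped.append(victim)
        cols.remove(victim)
    return matrix[cols], dropped


def center_scale(
    matrix: pd.DataFrame,
    fit: tuple[pd.Series, pd.Series] | None = None,
) -> tuple[pd.DataFrame, tuple[pd.Series, pd.Series]]:
    """Standardise columns to (x − mean)/SD.

    With ``fit`` given (means, SDs from a training fit), those statistics
    are applied unchanged — test data is never refit.
    """
    if fit is None:
        means = matrix.mean()
        sds = matrix.std(ddof=1)
    else:
        means, sds = fit
        missing = [c for c in matrix.columns if c not in means.index]
        if missing:
            raise ValueError(f"fit lacks statistics for column(s) {missing}")
        means = means[matrix.columns]
        sds = sds[matrix.columns]
    if (sds == 0).any():
        zero = [c for c in matrix.columns if sds[c] == 0]
        raise ValueError(f"zero-SD column(s) {zero} cannot be scaled")
    return (matrix - means) / sds, (means, sds)


@dataclass
class FeaturePipeline:
    """Fit-on-train / apply-to-anything feature filter and scaler.

    Parameters mirror the package defaults: SD threshold 0.3 for the
    near-zero-variance filter and |r| cutoff 0.85 for the correlation
    filter. ``scale_binary=True`` extends standardisation to fingerprint
    columns (off by default so they stay 0/1).
    """

    sd_threshold: float = 0.3
    corr_cutoff: float = 0.85
    scale_binary: bool = False
    correlate_binary: bool = False

    dropped_nzv: list[str] = field(default_factory=list)
    dropped_lincomb: list[str] = field(default_factory=list)
    dropped_corr: list[str] = field(default_factory=list)
    kept_columns: list[str] = field(default_factory=list)
    center: pd.Series | None = None
    scale: pd.Series | None = None
    _scaled_cols: list[str] = field(default_factory=list)
    _fitted: bool = False

    def fit(self, matrix: pd.DataFrame, binary_columns: Sequence[str] = ()) -> "FeaturePipeline":
        binary = [c for c in binary_columns if c in matrix.columns]
        numeric = [c for c in matrix.columns if c not in set(binary)]

        kept, self.dropped_nzv = nzv_filter(matrix, self.sd_threshold)
        bin_kept = [c for c in binary if c in kept.columns]
        num_kept = [c for c in numeric if c in kept.columns]

        _, lc_dropped = lincomb_filter(kept)
        self.dropped_lincomb = lc_dropped
        bin_kept = [c for c in bin_kept if c not in set(lc_dropped)]
        num_kept = [c for c in num_kept if c not in set(lc_dropped)]

        corr_cols = num_kept + (bin_kept if self.correlate_binary else [])
        if len(corr_cols) >= 2:
            _, self.dropped_corr = correlation_filter(kept[corr_cols], self.corr_cutoff)
        else:
            self.dropped_corr = []
        bin_kept = [c for c in bin_kept if c not in set(self.dropped_corr)]
        num_kept = [c for c in num_kept if c not in set(self.dropped_corr)]

        # preserve original column order
        kept_set = set(num_kept) | set(bin_kept)
        self.kept_columns = [c for c in matrix.columns if c in kept_set]
        self._scaled_cols = num_kept + (bin_kept if self.scale_binary else [])
        if self._scaled_cols:
            _, (self.center, self.scale) = center_scale(matrix[self._scaled_cols])
        else:
            self.center, self.scale = pd.Series(dtype=float), pd.Series(dtype=float)
        self._fitted = True
        return self

    def transform(self, matrix: pd.DataFrame) -> pd.DataFrame:
        if not self._fitted:
            raise RuntimeError("pipeline not fitted")
        missing = [c for c in self.kept_columns if c not in matrix.columns]
        if missing:
            raise ValueError(f"matrix lacks fitted column(s) {missing}")
        out = matrix[self.kept_columns].copy()
        if self._scaled_cols:
            scaled, _ = center_scale(out[self._scaled_cols], (self.center, self.scale))
            out[self._scaled_cols] = scaled
        return out

    def fit_transform(
        self, matrix: pd.DataFrame, binary_columns: Sequence[str] = ()
    ) -> pd.DataFrame:
        return self.fit(matrix, binary_columns).transform(matrix)

    def to_text(self, path: str | Path) -> None:
        """Serialize the fit (dropped sets, center/scale) for exact reuse."""
        with open(path, "w") as fh:
            fh.write(f"sd_threshold\t{self.sd_threshold}\n")
            fh.write(f"corr_cutoff\t{self.corr_cutoff}\n")
            for tag, names in (
                ("dropped_nzv", self.dropped_nzv),
                ("dropped_lincomb", self.dropped_lincomb),
                ("dropped_corr", self.dropped_corr),
                ("kept", self.kept_columns),
                ("scaled", self._scaled_cols),
            ):
                fh.write(f"{tag}\t{','.join(names)}\n")
            for col in self._scaled_cols:
                fh.write(f"stat\t{col}\t{float(self.center[col])!r}\t{float(self.scale[col])!r}\n")

    @classmethod
    def from_text(cls, path: str | Path) -> "FeaturePipeline":
        pipe = cls()
        center: dict[str, float] = {}
        scale: dict[str, float] = {}
        with open(path) as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                key = parts[0]
                if key == "sd_threshold":
                    pipe.sd_threshold = float(parts[1])
                elif key == "corr_cutoff":
                    pipe.corr_cutoff = float(parts[1])
                elif key in ("dropped_nzv", "dropped_lincomb", "dropped_corr", "kept", "scaled"):
                    names = parts[1].split(",") if len(parts) > 1 and parts[1] else []
                    if key == "kept":
                        pipe.kept_columns = names
                    elif key == "scaled":
                        pipe._scaled_cols = names
                    else:
                        setattr(pipe, key, names)
                elif key == "stat":
                    center[parts[1]] = float(parts[2])
                    scale[parts[1]] = float(parts[3])
        pipe.center = pd.Series(center, dtype=float)
        pipe.scale = pd.Series(scale, dtype=float)
        pipe._fitted = True
        return pipe


def reference_preset() -> list[str]:
    """The package's 40-feature reference preset: 4 nucleotide counts, 21
    distance descriptors (7 motifs × 3), 4 graph features and 11 positional
    fingerprints. Rg is deliberately absent (it is collinear with
    PMI1 + PMI2 and falls to correlation filtering downstream)."""
    names = ["A", "T", "G", "C"]
    for m in ("CG", "AG", "GG", "CC", "TCT", "TTC", "TGT"):
        names += [f"d_{m}2_1", f"d_{m}3_1", f"d_{m}3_2"]
    names += ["PMI1", "PMI2", "Mu_x", "Mu_y"]
    names += ["CG1", "GC1", "GT1", "GT18", "GCG6", "GT22",
              "GT21", "CGCG5", "GC5", "GT12", "TC9"]
    return names
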