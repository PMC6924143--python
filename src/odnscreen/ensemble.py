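"""The down-sampling random-forest consensus classifier.

One classifier is trained per down-sampling repetition of a
:class:`~odnscreen.resampling.SplitPlan`; each member carries its own
fingerprint dictionary and feature-pipeline fit (built from that member's
training ODNs only, so no information from a member's held-out test set or
from screening candidates ever reaches its fit). A candidate's consensus
score is the mean of the members' high-class probabilities; scores at or
above the decision threshold (default 0.5, boundary inclusive) are called
high, and candidates are ranked by score with ties broken by id.

The random forest's mtry hyperparameter (features considered per split) is
tuned by stratified cross-validation on each member's training set over a
grid around sqrt(p). Baseline learner families (gradient boosting,
shrinkage discriminant analysis, RBF support-vector machine, single-layer
neural network) share the same protocol for benchmarking; they are
comparison plumbing, not the deliverable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.calibration import CalibratedClassifierCV
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

from .descriptors import DEFAULT_DISTANCE_MOTIFS, featurize
from .evaluation import MetricSet, confusion, metrics
from .motifs import FingerprintDictionary, build_dictionary
from .pipeline import FeaturePipeline
from .records import HIGH, LOW, OdnRecord, split_by_label
from .resampling import SplitPlan, kfold

FAMILIES = ("rf", "gbm", "sda", "svm", "nn")


def default_mtry_grid(n_features: int) -> list[int]:
    """{floor(sqrt(p)/2), floor(sqrt(p)), floor(2 sqrt(p))}, deduplicated,
    clamped to [1, p] and sorted."""
    root = np.sqrt(n_features)
    cand = (int(np.floor(root / 2)), int(np.floor(root)), int(np.floor(2 * root)))
    return sorted({min(max(c, 1), n_features) for c in cand})


def _proba_high(model, X: np.ndarray) -> np.ndarray:
    idx = list(model.classes_).index(HIGH)
    return model.predict_proba(X)[:, idx]


def _cv_balanced_accuracy(
    make_model, X: pd.DataFrame, y: Sequence[str], k: int, seed: int
) -> float:
    folds = kfold(list(X.index), list(y), k=k, seed=seed)
    y_arr = pd.Series(list(y), index=X.index)
    preds: dict[str, str] = {}
    for f in range(k):
        test_ids = [i for i in X.index if folds[i] == f]
        train_ids = [i for i in X.index if folds[i] != f]
        model = make_model()
        model.fit(X.loc[train_ids].to_numpy(), y_arr.loc[train_ids].to_numpy())
        for i, p in zip(test_ids, model.predict(X.loc[test_ids].to_numpy())):
            preds[i] = p
    cm = confusion([preds[i] for i in X.index], list(y_arr))
    ba = metrics(cm).balanced_accuracy
    return -1.0 if ba is None else ba


def train_rf(
    X: pd.DataFrame,
    y: Sequence[str],
    mtry_grid: Sequence[int] | None = None,
    k: int = 5,
    seed: int = 0,
    n_trees: int = 500,
) -> tuple[RandomForestClassifier, int, pd.DataFrame]:
    """Tune mtry by k-fold CV balanced accuracy, refit the winner on all
    training data. Returns (model, best_mtry, cv_table). Ties go to the
    smaller mtry."""
    classes = set(y)
    if len(classes) < 2:
        raise ValueError("training data must contain both classes")
    p = X.shape[1]
    grid = list(mtry_grid) if mtry_grid is not None else default_mtry_grid(p)
    if any(m > p for m in grid):
        raise ValueError(f"mtry candidate exceeds feature count {p}")
    rows = []
    for mtry in grid:
        ba = _cv_balanced_accuracy(
            lambda: RandomForestClassifier(
                n_estimators=n_trees, max_features=mtry, criterion="gini",
                oob_score=True, random_state=seed,
            ),
            X, y, k=k, seed=seed,
        )
        rows.append({"mtry": mtry, "cv_balanced_accuracy": ba})
    cv_table = pd.DataFrame(rows)
    best = int(cv_table.sort_values(["cv_balanced_accuracy", "mtry"],
                                    ascending=[False, True]).iloc[0]["mtry"])
    model = RandomForestClassifier(
        n_estimators=n_trees, max_features=best, criterion="gini",
        oob_score=True, random_state=seed,
    )
    model.fit(X.to_numpy(), np.asarray(y))
    return model, best, cv_table


def _make_baseline(family: str, params: Mapping, seed: int):
    if family == "rf":
        return RandomForestClassifier(
            n_estimators=params.get("n_trees", 500),
            max_features=params.get("mtry", "sqrt"),
            criterion="gini", random_state=seed,
        )
    if family == "gbm":
        return GradientBoostingClassifier(
            n_estimators=params.get("n_trees", 100),
            learning_rate=params.get("learning_rate", 0.1),
            max_depth=params.get("max_depth", 3),
            random_state=seed,
        )
    if family == "sda":
        return LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")
    if family == "svm":
        # Platt-calibrated RBF SVM so every family exposes predict_proba
        return CalibratedClassifierCV(
            SVC(kernel="rbf", C=params.get("C", 1.0), gamma="scale",
                random_state=seed),
            ensemble=False,
        )
    if family == "nn":
        return MLPClassifier(
            hidden_layer_sizes=(params.get("hidden", 8),),
            max_iter=2000, random_state=seed,
        )
    raise ValueError(f"unsupported learner family {family!r} (one of {FAMILIES})")


def train_baseline(
    family: str,
    X: pd.DataFrame,
    y: Sequence[str],
    k: int = 5,
    seed: int = 0,
    params: Mapping | None = None,
):
    """Fit one comparison learner with the shared CV protocol; returns
    (model, cv_balanced_accuracy)."""
    if len(set(y)) < 2:
        raise ValueError("training data must contain both classes")
    params = dict(params or {})
    ba = _cv_balanced_accuracy(lambda: _make_baseline(family, params, seed), X, y, k, seed)
    model = _make_baseline(family, params, seed)
    model.fit(X.to_numpy(), np.asarray(y))
    return model, ba


@dataclass
class EnsembleMember:
    """One fitted repeat: its dictionary, pipeline fit and classifier."""

    index: int
    seed: int
    dictionary: FingerprintDictionary
    pipeline: FeaturePipeline
    model: object
    mtry: int | None = None
    test_metrics: MetricSet | None = None


@dataclass
class TrainedEnsemble:
    """The consensus classifier: fitted members plus the decision rule."""

    members: list[EnsembleMember]
    distance_motifs: tuple[str, ...] = DEFAULT_DISTANCE_MOTIFS
    consensus_rule: str = "mean_probability"  # or "majority_vote"
    decision_threshold: float = 0.5

    @property
    def n_members(self) -> int:
        return len(self.members)

    def member_test_metrics(self) -> pd.DataFrame:
        rows = []
        for m in self.members:
            tm = m.test_metrics
            rows.append({
                "member": m.index, "seed": m.seed, "mtry": m.mtry,
                "balanced_accuracy": None if tm is None else tm.balanced_accuracy,
                "mcc": None if tm is None else tm.mcc,
                "sensitivity": None if tm is None else tm.sensitivity,
                "specificity": None if tm is None else tm.specificity,
                "precision": None if tm is None else tm.precision,
            })
        return pd.DataFrame(rows)

    def save(self, directory: str | Path) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        manifest = {
            "n_members": self.n_members,
            "distance_motifs": list(self.distance_motifs),
            "consensus_rule": self.consensus_rule,
            "decision_threshold": self.decision_threshold,
            "members": [
                {"index": m.index, "seed": m.seed, "mtry": m.mtry}
                for m in self.members
            ],
        }
        (d / "manifest.json").write_text(json.dumps(manifest, indent=2))
        for m in self.members:
            m.dictionary.to_tsv(d / f"member{m.index:02d}.dict.tsv")
            m.pipeline.to_text(d / f"member{m.index:02d}.pipeline.txt")
            joblib.dump(m.model, d / f"member{m.index:02d}.model.joblib")

    @classmethod
    def load(cls, directory: str | Path) -> "TrainedEnsemble":
        d = Path(directory)
        manifest = json.loads((d / "manifest.json").read_text())
        members = []
        for info in manifest["members"]:
            i = info["index"]
            members.append(EnsembleMember(
                index=i, seed=info["seed"],
                dictionary=FingerprintDictionary.from_tsv(d / f"member{i:02d}.dict.tsv"),
                pipeline=FeaturePipeline.from_text(d / f"member{i:02d}.pipeline.txt"),
                model=joblib.load(d / f"member{i:02d}.model.joblib"),
                mtry=info.get("mtry"),
            ))
        return cls(
            members=members,
            distance_motifs=tuple(manifest["distance_motifs"]),
            consensus_rule=manifest["consensus_rule"],
            decision_threshold=manifest["decision_threshold"],
        )


def _fit_member(
    rep_index: int,
    rep_seed: int,
    train_records: list[OdnRecord],
    test_records: list[OdnRecord],
    distance_motifs: Sequence[str],
    dict_threshold: float,
    tune_k: int,
    n_trees: int,
    shared: tuple[FingerprintDictionary, FeaturePipeline] | None,
) -> EnsembleMember:
    if shared is None:
        high, low = split_by_label(train_records)
        dictionary = build_dictionary(high, low, threshold=dict_threshold)
        X_raw = featurize(train_records, dictionary, distance_motifs)
        pipe = FeaturePipeline().fit(X_raw, binary_columns=dictionary.names)
    else:
        dictionary, pipe = shared
        X_raw = featurize(train_records, dictionary, distance_motifs)
    X = pipe.transform(X_raw)
    y = [r.label for r in train_records]
    model, mtry, _ = train_rf(X, y, k=tune_k, seed=rep_seed, n_trees=n_trees)
    member = EnsembleMember(
        index=rep_index, seed=rep_seed, dictionary=dictionary,
        pipeline=pipe, model=model, mtry=mtry,
    )
    if test_records:
        Xt = pipe.transform(featurize(test_records, dictionary, distance_motifs))
        pred = model.predict(Xt.to_numpy())
        member.test_metrics = metrics(confusion(list(pred), [r.label for r in test_records]))
    return member


def ensemble_fit(
    records: Sequence[OdnRecord],
    plan: SplitPlan,
    distance_motifs: Sequence[str] = DEFAULT_DISTANCE_MOTIFS,
    dict_threshold: float = 0.10,
    tune_k: int = 5,
    n_trees: int = 500,
    shared_fit: bool = False,
    decision_threshold: float = 0.5,
    consensus_rule: str = "mean_probability",
) -> TrainedEnsemble:
    """Train one member per plan repetition.

    By default each member builds its own fingerprint dictionary and
    feature-pipeline fit from its training ODNs (strict leakage control).
    ``shared_fit=True`` instead builds one global dictionary and pipeline
    from the full labelled dataset and shares it across members.
    """
    by_id = {r.id: r for r in records}
    shared = None
    if shared_fit:
        high, low = split_by_label(records)
        dictionary = build_dictionary(high, low, threshold=dict_threshold)
        X_all = featurize(list(records), dictionary, distance_motifs)
        shared = (dictionary, FeaturePipeline().fit(X_all, binary_columns=dictionary.names))
    members = [
        _fit_member(
            rep.index, rep.seed,
            [by_id[i] for i in rep.train_ids],
            [by_id[i] for i in rep.test_ids],
            distance_motifs, dict_threshold, tune_k, n_trees, shared,
        )
        for rep in plan.repeats
    ]
    return TrainedEnsemble(
        members=members,
        distance_motifs=tuple(distance_motifs),
        consensus_rule=consensus_rule,
        decision_threshold=decision_threshold,
    )


def ensemble_predict(
    candidates: Sequence[OdnRecord], ensemble: TrainedEnsemble
) -> pd.DataFrame:
    """Consensus predictions, ranked.

    Columns: id, sequence, score (mean high-class probability), votes
    (members predicting high), label (high iff score ≥ threshold, boundary
    inclusive), rank (1-based by descending score, ties by id).
    """
    if not ensemble.members:
        raise ValueError("ensemble has no members")
    probas = np.zeros((len(candidates), ensemble.n_members))
    for j, m in enumerate(ensemble.members):
        X = m.pipeline.transform(
            featurize(list(candidates), m.dictionary, ensemble.distance_motifs)
        )
        probas[:, j] = _proba_high(m.model, X.to_numpy())
    votes = (probas >= 0.5).sum(axis=1).astype(int)
    if ensemble.consensus_rule == "majority_vote":
        score = votes / ensemble.n_members
    else:
        score = probas.mean(axis=1)
    df = pd.DataFrame({
        "id": [c.id for c in candidates],
        "sequence": [c.sequence for c in candidates],
        "score": score,
        "votes": votes,
    })
    df["label"] = np.where(df["score"] >= ensemble.decision_threshold, HIGH, LOW)
    df = df.sort_values(["score", "id"], ascending=[False, True],
                        kind="mergesort").reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df


def benchmark(
    records: Sequence[OdnRecord],
    plan: SplitPlan,
    families: Sequence[str] = FAMILIES,
    k_values: Sequence[int] = (5, 10, 15, 20),
    distance_motifs: Sequence[str] = DEFAULT_DISTANCE_MOTIFS,
    dict_threshold: float = 0.10,
    n_trees: int = 500,
) -> pd.DataFrame:
    """Held-out metrics for every (family, k, repeat) combination.

    Each repetition reuses the plan's memberships; every family is trained
    on the same member training matrix (per-member dictionary and pipeline,
    as in :func:`ensemble_fit`) and evaluated on the member's test set.
    Returns one row per (family, k, repeat) with balanced_accuracy and mcc,
    ready for :func:`odnscreen.evaluation.aggregate`.
    """
    by_id = {r.id: r for r in records}
    rows = []
    for rep in plan.repeats:
        train_records = [by_id[i] for i in rep.train_ids]
        test_records = [by_id[i] for i in rep.test_ids]
        high, low = split_by_label(train_records)
        dictionary = build_dictionary(high, low, threshold=dict_threshold)
        pipe = FeaturePipeline().fit(
            featurize(train_records, dictionary, distance_motifs),
            binary_columns=dictionary.names,
        )
        X = pipe.transform(featurize(train_records, dictionary, distance_motifs))
        Xt = pipe.transform(featurize(test_records, dictionary, distance_motifs))
        y = [r.label for r in train_records]
        yt = [r.label for r in test_records]
        for family in families:
            for k in k_values:
                if family == "rf":
                    model, _, _ = train_rf(X, y, k=k, seed=rep.seed, n_trees=n_trees)
                else:
                    model, _ = train_baseline(family, X, y, k=k, seed=rep.seed)
                pred = model.predict(Xt.to_numpy())
                ms = metrics(confusion(list(pred), yt))
                rows.append({
                    "family": family, "k": k, "repeat": rep.index,
                    "balanced_accuracy": ms.balanced_accuracy, "mcc": ms.mcc,
                })
    return pd.DataFrame(rows)


def select_top(ranked: pd.DataFrame, n: int = 100) -> pd.DataFrame:
    """First ``n`` rows of a ranked prediction table (ties already broken
    by id during ranking)."""
    if n < 0 or n > len(ranked):
        raise ValueError(f"n={n} out of range for {len(ranked)} candidates")
    return ranked.iloc[:n].reset_index(drop=True)
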