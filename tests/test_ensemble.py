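import numpy as np
import pandas as pd
import pytest

from odnscreen import (
    OdnRecord,
    TrainedEnsemble,
    assign_labels,
    benchmark,
    build_dictionary,
    build_plan,
    default_mtry_grid,
    ensemble_fit,
    ensemble_predict,
    featurize,
    select_top,
    split_by_label,
    train_baseline,
    train_rf,
    FeaturePipeline,
    aggregate,
    random_odns,
)
from odnscreen.records import HIGH, LOW


def positional_dataset(n: int, seed: int) -> list[OdnRecord]:
    """Separable synthetic ODNs: the high class carries CGCG written at
    position 5, a signal the positional fingerprint dictionary can see."""
    recs = random_odns(n, length=24, seed=seed)
    out = []
    for i, r in enumerate(recs):
        if i % 2 == 0:
            seq = r.sequence[:4] + "CGCG" + r.sequence[8:]
            out.append(OdnRecord(r.id, seq, activity=0.8))
        else:
            seq = r.sequence[:4] + "ATTA" + r.sequence[8:]
            out.append(OdnRecord(r.id, seq, activity=0.1))
    return assign_labels(out)


def member_matrix(records):
    high, low = split_by_label(records)
    d = build_dictionary(high, low)
    X_raw = featurize(records, d)
    pipe = FeaturePipeline().fit(X_raw, binary_columns=d.names)
    return pipe.transform(X_raw), [r.label for r in records]


class TestMtryGrid:
    def test_sqrt_based_grid(self):
        assert default_mtry_grid(40) == [3, 6, 12]
        assert default_mtry_grid(1) == [1]
        assert all(1 <= m <= 9 for m in default_mtry_grid(9))


class TestTrainRf:
    def test_learns_positional_signal(self):
        records = positional_dataset(120, seed=0)
        X, y = member_matrix(records)
        model, mtry, cv = train_rf(X, y, k=3, seed=0, n_trees=100)
        assert mtry in cv.mtry.values
        assert cv.cv_balanced_accuracy.max() > 0.9
        # training-set predictions recover the labels
        pred = model.predict(X.to_numpy())
        assert (pred == np.array(y)).mean() > 0.95

    def test_deterministic(self):
        records = positional_dataset(60, seed=1)
        X, y = member_matrix(records)
        m1, mtry1, _ = train_rf(X, y, k=2, seed=5, n_trees=50)
        m2, mtry2, _ = train_rf(X, y, k=2, seed=5, n_trees=50)
        assert mtry1 == mtry2
        probe = X.to_numpy()
        assert (m1.predict_proba(probe) == m2.predict_proba(probe)).all()

    def test_single_class_is_error(self):
        records = positional_dataset(20, seed=2)
        X, _ = member_matrix(records)
        with pytest.raises(ValueError):
            train_rf(X, [HIGH] * len(X), k=2, seed=0, n_trees=10)

    def test_mtry_exceeding_features_is_error(self):
        records = positional_dataset(20, seed=3)
        X, y = member_matrix(records)
        with pytest.raises(ValueError):
            train_rf(X, y, mtry_grid=[X.shape[1] + 1], k=2, seed=0, n_trees=10)


class TestBaselines:
    @pytest.fixture
    def gaussian_toy(self, rng):
        n = 60
        X = pd.DataFrame(
            np.vstack([rng.normal(-2, 1, (n, 2)), rng.normal(2, 1, (n, 2))]),
            columns=["f1", "f2"],
            index=[f"s{i}" for i in range(2 * n)],
        )
        y = [HIGH] * n + [LOW] * n
        return X, y

    def test_sda_separates_gaussians(self, gaussian_toy):
        X, y = gaussian_toy
        model, cv_ba = train_baseline("sda", X, y, k=3, seed=0)
        assert cv_ba > 0.9
        assert (model.predict(X.to_numpy()) == np.array(y)).mean() > 0.9

    @pytest.mark.parametrize("family", ["rf", "gbm", "svm", "nn"])
    def test_probability_contract(self, gaussian_toy, family):
        X, y = gaussian_toy
        model, _ = train_baseline(family, X, y, k=2, seed=0,
                                  params={"n_trees": 30})
        proba = model.predict_proba(X.to_numpy())
        assert proba.shape == (len(X), 2)
        assert np.allclose(proba.sum(axis=1), 1)
        assert set(model.classes_) == {HIGH, LOW}

    def test_unknown_family(self, gaussian_toy):
        X, y = gaussian_toy
        with pytest.raises(ValueError, match="family"):
            train_baseline("tree-of-heaven", X, y)


@pytest.fixture(scope="module")
def small_ensemble():
    records = positional_dataset(100, seed=4)
    plan = build_plan(records, n_repeats=2, k=2, seed=4)
    ens = ensemble_fit(records, plan, tune_k=2, n_trees=50)
    return records, ens


class TestEnsembleFit:
    def test_one_member_per_repeat_with_metrics(self, small_ensemble):
        _, ens = small_ensemble
        assert ens.n_members == 2
        table = ens.member_test_metrics()
        assert len(table) == 2
        assert table.balanced_accuracy.notna().all()
        # separable data: members should classify their held-out sets well
        assert table.balanced_accuracy.mean() > 0.85

    def test_single_repeat_degenerates(self):
        records = positional_dataset(60, seed=5)
        plan = build_plan(records, n_repeats=1, k=2, seed=5)
        ens = ensemble_fit(records, plan, tune_k=2, n_trees=30)
        assert ens.n_members == 1

    def test_shared_fit_shares_dictionary(self):
        records = positional_dataset(60, seed=6)
        plan = build_plan(records, n_repeats=2, k=2, seed=6)
        ens = ensemble_fit(records, plan, tune_k=2, n_trees=30, shared_fit=True)
        assert ens.members[0].dictionary.tokens == ens.members[1].dictionary.tokens


class TestEnsemblePredict:
    def test_scores_bounded_and_order_invariant(self, small_ensemble):
        _, ens = small_ensemble
        cand = random_odns(30, seed=9)
        ranked = ensemble_predict(cand, ens)
        assert ranked.score.between(0, 1).all()
        assert ranked.votes.between(0, ens.n_members).all()
        shuffled = ensemble_predict(cand[::-1], ens)
        pd.testing.assert_frame_equal(ranked, shuffled)
        assert ranked["rank"].tolist() == list(range(1, 31))

    def test_planted_candidates_outrank_background(self, small_ensemble):
        _, ens = small_ensemble
        background = random_odns(20, seed=10)
        planted = [
            OdnRecord(f"P{i}", r.sequence[:4] + "CGCG" + r.sequence[8:])
            for i, r in enumerate(random_odns(20, seed=11))
        ]
        ranked = ensemble_predict(background + planted, ens)
        top10 = set(ranked.head(10).id)
        assert sum(i.startswith("P") for i in top10) >= 8

    def test_save_load_round_trip(self, small_ensemble, tmp_path):
        _, ens = small_ensemble
        ens.save(tmp_path / "model")
        back = TrainedEnsemble.load(tmp_path / "model")
        cand = random_odns(15, seed=12)
        pd.testing.assert_frame_equal(
            ensemble_predict(cand, ens), ensemble_predict(cand, back)
        )


class _FixedProba:
    classes_ = np.array([HIGH, LOW])

    def __init__(self, p_high):
        self.p = p_high

    def predict_proba(self, X):
        n = len(X)
        return np.column_stack([np.full(n, self.p), np.full(n, 1 - self.p)])


def stub_ensemble(probs):
    records = positional_dataset(30, seed=13)
    high, low = split_by_label(records)
    d = build_dictionary(high, low)
    pipe = FeaturePipeline().fit(featurize(records, d), binary_columns=d.names)
    from odnscreen.ensemble import EnsembleMember

    members = [
        EnsembleMember(index=i, seed=i, dictionary=d, pipeline=pipe,
                       model=_FixedProba(p))
        for i, p in enumerate(probs)
    ]
    return TrainedEnsemble(members=members)


class TestConsensusRule:
    def test_unanimous_members(self):
        ens = stub_ensemble([1.0] * 20)
        out = ensemble_predict(random_odns(3, seed=0), ens)
        assert (out.score == 1).all() and (out.votes == 20).all()
        assert (out.label == HIGH).all()

    def test_even_split_is_high_at_threshold(self):
        ens = stub_ensemble([1.0] * 10 + [0.0] * 10)
        out = ensemble_predict(random_odns(3, seed=0), ens)
        assert (out.score == 0.5).all()
        assert (out.label == HIGH).all()  # threshold is inclusive

    def test_majority_vote_rule(self):
        ens = stub_ensemble([0.9] * 3 + [0.1] * 17)
        ens.consensus_rule = "majority_vote"
        out = ensemble_predict(random_odns(2, seed=0), ens)
        assert np.allclose(out.score, 3 / 20)
        assert (out.label == LOW).all()

    def test_ties_broken_by_id(self):
        ens = stub_ensemble([0.7] * 5)
        cand = random_odns(10, seed=14)
        out = ensemble_predict(cand, ens)
        assert out.id.tolist() == sorted(r.id for r in cand)
        top = select_top(out, 4)
        assert top.id.tolist() == sorted(r.id for r in cand)[:4]


class TestSelectTop:
    def test_bounds(self, small_ensemble):
        _, ens = small_ensemble
        ranked = ensemble_predict(random_odns(10, seed=15), ens)
        assert len(select_top(ranked, 0)) == 0
        assert len(select_top(ranked, 10)) == 10
        with pytest.raises(ValueError):
            select_top(ranked, 11)


class TestBenchmark:
    def test_shape_and_aggregation(self):
        records = positional_dataset(80, seed=16)
        plan = build_plan(records, n_repeats=2, k=2, seed=16)
        results = benchmark(records, plan, families=("rf", "sda"), k_values=(2,),
                            n_trees=30)
        assert len(results) == 4  # 2 families x 1 k x 2 repeats
        summary = aggregate(results)
        assert len(summary) == 2
        assert {"mean_ba", "sd_ba", "max_mcc"} <= set(summary.columns)
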