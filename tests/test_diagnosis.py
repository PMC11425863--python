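import numpy as np
import pandas as pd
import pytest

from fluidprint.core_io import FeatureMatrix
from fluidprint.diagnosis import (
    SearchResult,
    cascade_classify,
    CascadeModel,
    CascadeStage,
    concat_fingerprints,
    elastic_net_select,
    evaluate_metrics,
    model_search,
    rebalance,
    roc_auc,
    stratified_split,
)
from fluidprint.errors import (
    ConfigError,
    ContractError,
    PairingError,
    UndefinedMetricError,
)


def _clinical(n, groups, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame({
        "sample_id": [f"s{i}" for i in range(n)],
        "group": groups,
        "age": rng.integers(40, 70, n),
        "sex": rng.choice(["F", "M"], n),
        "stage": ["none" if g in ("HC", "AML") else "I" for g in groups],
        "dfs_time": np.nan,
        "event": np.nan,
    })


class TestConcat:
    def test_feature_axis_fusion(self, matrix_factory):
        smf = matrix_factory(np.ones((10, 3)), labels=["S100.0", "S200.0", "S300.0"])
        umf = matrix_factory(np.ones((10, 2)), labels=["U100.0", "U150.0"])
        fused = concat_fingerprints(smf, umf)
        assert fused.n_samples() == 10 and fused.n_features() == 5
        assert fused.feature_labels[:3] == smf.feature_labels
        assert fused.fluid_of_feature == ["serum"] * 3 + ["urine"] * 2

    def test_empty_urine_block_is_identity(self, matrix_factory):
        smf = matrix_factory(np.ones((4, 2)))
        umf = FeatureMatrix(pd.DataFrame(index=smf.sample_ids))
        fused = concat_fingerprints(smf, umf)
        assert fused.frame.equals(smf.frame)

    def test_id_mismatch_lists_symmetric_difference(self, matrix_factory):
        smf = matrix_factory(np.ones((2, 1)), sample_ids=["a", "b"])
        umf = matrix_factory(np.ones((2, 1)), sample_ids=["a", "c"],
                             labels=["U100.0"])
        with pytest.raises(PairingError, match="b.*c|c.*b"):
            concat_fingerprints(smf, umf)


class TestStratifiedSplit:
    def test_exact_stratification_7_3(self):
        clinical = _clinical(100, ["HC"] * 50 + ["ccRCC"] * 50)
        plan = stratified_split(clinical, (7, 3), seed=0)
        assert len(plan.train_ids) == 70 and len(plan.test_ids) == 30
        g = clinical.set_index("sample_id")["group"]
        assert (g.loc[plan.train_ids] == "HC").sum() == 35
        assert (g.loc[plan.test_ids] == "HC").sum() == 15
        assert plan.p_age > 0.05 and plan.p_sex > 0.05

    def test_two_to_one_split_on_99(self):
        clinical = _clinical(99, ["HC"] * 66 + ["ccRCC"] * 33)
        plan = stratified_split(clinical, (2, 1), seed=1)
        assert len(plan.train_ids) == 66 and len(plan.test_ids) == 33

    def test_same_seed_identical_plan(self):
        clinical = _clinical(60, ["HC"] * 30 + ["ccRCC"] * 30)
        p1 = stratified_split(clinical, seed=5)
        p2 = stratified_split(clinical, seed=5)
        assert p1.train_ids == p2.train_ids and p1.test_ids == p2.test_ids


class TestElasticNetSelect:
    def test_vanishing_penalty_approaches_ols(self, rng):
        n, p = 200, 5
        X = rng.normal(size=(n, p))
        beta = np.array([1.0, -2.0, 0.5, 0.0, 3.0])
        y = X @ beta + rng.normal(0, 0.1, n)
        rep = elastic_net_select(
            X, y, alphas=(1e-8,), l1_ratios=(0.5,), coef_threshold=0.05, seed=0
        )
        Xs = (X - X.mean(0)) / X.std(0)
        ols = np.linalg.lstsq(
            np.c_[np.ones(n), Xs], y, rcond=None
        )[0][1:]
        np.testing.assert_allclose(rep.coefficients.to_numpy(), ols, atol=1e-2)

    def test_planted_features_recovered(self, rng):
        X = rng.normal(size=(300, 60))
        y = rng.integers(0, 2, 300)
        X[:, :5] += y[:, None] * 0.954  # single-feature AUC ~ 0.75
        rep = elastic_net_select(X, y.astype(float), seed=3)
        recall = len(set(rep.selected) & {f"x{j}" for j in range(5)}) / 5
        assert recall >= 0.8

    def test_pure_noise_selects_few(self, rng):
        import warnings

        counts = []
        for seed in range(5):
            X = rng.normal(size=(200, 100))
            y = rng.integers(0, 2, 200).astype(float)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                rep = elastic_net_select(X, y, seed=seed)
            counts.append(len(rep.selected))
        assert max(counts) <= 5


class TestModelSearch:
    def test_separable_data_reaches_high_outer_auc(self, rng):
        n = 120
        X = rng.normal(size=(n, 4))
        y = (X[:, 0] + X[:, 1] > 0).astype(int)
        X[:, :2] += y[:, None] * 3.0  # wide margin
        res = model_search(X, y, zoo=("LR", "LDA"), folds=5, seed=0)
        assert np.mean(res.outer_fold_auc) >= 0.95

    def test_label_permutation_gives_chance_auc(self, rng):
        X = rng.normal(size=(100, 10))
        y = (X[:, 0] > 0).astype(int)
        aucs = []
        for seed in range(10):
            yp = np.random.default_rng(seed).permutation(y)
            res = model_search(X, yp, zoo=("LR",), folds=5, seed=seed)
            aucs.append(np.mean(res.outer_fold_auc))
        assert 0.4 <= np.mean(aucs) <= 0.6

    def test_determinism(self, rng):
        X = rng.normal(size=(80, 6))
        y = (X[:, 0] + rng.normal(0, 1, 80) > 0).astype(int)
        r1 = model_search(X, y, zoo=("LR", "DT"), folds=4, seed=11)
        r2 = model_search(X, y, zoo=("LR", "DT"), folds=4, seed=11)
        assert r1.algorithm == r2.algorithm
        assert r1.hyperparameters == r2.hyperparameters
        assert r1.outer_fold_auc == r2.outer_fold_auc

    def test_too_few_per_class_raises(self, rng):
        X = rng.normal(size=(12, 3))
        y = np.r_[np.zeros(9), np.ones(3)].astype(int)
        with pytest.raises(ConfigError):
            model_search(X, y, zoo=("LR",), folds=5)


class TestRebalance:
    def test_oversample_to_parity_with_duplicates_only(self, rng):
        X = rng.normal(size=(120, 3))
        y = np.r_[np.zeros(100), np.ones(20)].astype(int)
        Xb, yb = rebalance(X, y, seed=0)
        assert (yb == 0).sum() == (yb == 1).sum() == 100
        minority_rows = {tuple(r) for r in X[100:]}
        assert all(tuple(r) in minority_rows for r in Xb[yb == 1])

    def test_balanced_input_unchanged(self, rng):
        X = rng.normal(size=(40, 2))
        y = np.r_[np.zeros(20), np.ones(20)].astype(int)
        Xb, yb = rebalance(X, y, seed=0)
        np.testing.assert_array_equal(Xb, X)

    def test_rejects_non_training_role(self, rng):
        X = rng.normal(size=(10, 2))
        y = np.r_[np.zeros(5), np.ones(5)]
        with pytest.raises(ContractError):
            rebalance(X, y, role="test")


class TestMetrics:
    def test_small_case_matches_pair_enumeration(self):
        # pairs: (0.9,0.7)+, (0.9,0.1)+, (0.6,0.7)-, (0.6,0.1)+ -> 3/4
        m = roc_auc(np.array([1, 1, 0, 0]), np.array([0.9, 0.6, 0.7, 0.1]))
        assert m == pytest.approx(0.75)

    def test_rank_auc_equals_brute_force_pair_counting(self, rng):
        for _ in range(20):
            n = int(rng.integers(6, 50))
            y = rng.integers(0, 2, n)
            if y.sum() in (0, n):
                continue
            s = rng.choice(np.linspace(0, 1, 11), n)  # force ties
            brute = _brute_auc(y, s)
            assert roc_auc(y, s) == pytest.approx(brute, abs=1e-12)

    def test_perfect_separation(self):
        y = np.array([0, 0, 1, 1])
        s = np.array([0.1, 0.2, 0.8, 0.9])
        metrics, ci, cm = evaluate_metrics(y, s, n_boot=200, seed=0)
        assert metrics["roc_auc"] == 1.0
        assert metrics["kappa"] == 1.0
        assert cm.loc["true_pos", "pred_pos"] == 2

    def test_random_scores_near_half(self, rng):
        y = rng.integers(0, 2, 1000)
        s = rng.random(1000)
        assert 0.45 <= roc_auc(y, s) <= 0.55

    def test_single_class_truth_rejected(self):
        with pytest.raises(UndefinedMetricError):
            evaluate_metrics(np.ones(5), np.linspace(0, 1, 5))

    def test_confusion_margins_match_class_counts(self, rng):
        y = rng.integers(0, 2, 60)
        s = rng.random(60)
        if y.sum() in (0, 60):
            y[0] = 1 - y[0]
        _, _, cm = evaluate_metrics(y, s, n_boot=50, seed=1)
        assert cm.sum(axis=1).tolist() == [(y == 0).sum(), (y == 1).sum()]


def _brute_auc(y, s):
    pos = s[y == 1]
    neg = s[y == 0]
    wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
    return wins / (len(pos) * len(neg))


class _StubModel:
    def __init__(self, proba):
        self._p = np.asarray(proba)

    def predict_proba(self, X):
        return np.tile(self._p, (len(X), 1))


def _stub_stage(proba, classes, features):
    return CascadeStage(
        SearchResult("stub", {}, [], _StubModel(proba), np.asarray(classes),
                     pd.DataFrame()),
        features, None,
    )


class TestCascadeRouting:
    def _cascade(self, p_tumor, p_malig, matrix_factory):
        feats = ["S100.0", "S101.0"]
        split = None
        from fluidprint.diagnosis import SplitPlan

        split = SplitPlan(["t0"], ["t1"], (7, 3), "group", 1.0, 1.0, True, 1)
        return CascadeModel(
            _stub_stage([1 - p_tumor, p_tumor], [0, 1], feats),
            _stub_stage([1 - p_malig, p_malig], [0, 1], feats),
            _stub_stage([0.2, 0.5, 0.3], ["ccRCC", "chRCC", "pRCC"], feats),
            split,
        )

    def test_low_tumor_probability_routes_to_hc(self, matrix_factory):
        cascade = self._cascade(0.1, 0.9, matrix_factory)
        m = matrix_factory(np.ones((3, 2)), labels=["S100.0", "S101.0"])
        out = cascade_classify(cascade, m)
        assert (out["label"] == "HC").all()
        assert out["p_malignant"].isna().all()
        assert out["p_ccRCC"].isna().all()

    def test_benign_routing_stops_at_aml(self, matrix_factory):
        cascade = self._cascade(0.9, 0.2, matrix_factory)
        m = matrix_factory(np.ones((2, 2)), labels=["S100.0", "S101.0"])
        out = cascade_classify(cascade, m)
        assert (out["label"] == "AML").all()
        assert out["p_ccRCC"].isna().all()

    def test_malignant_routing_takes_argmax_subtype(self, matrix_factory):
        cascade = self._cascade(0.9, 0.8, matrix_factory)
        m = matrix_factory(np.ones((2, 2)), labels=["S100.0", "S101.0"])
        out = cascade_classify(cascade, m)
        assert (out["label"] == "chRCC").all()
        assert np.allclose(out["p_chRCC"], 0.5)
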