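"""Loss assembly, constrained fitting and LOSO cross-validation."""

import numpy as np
import pytest
from scipy.optimize import approx_fprime

from gaitscore import (
    HyperplaneGaitScorer,
    InsufficientDataError,
    ModelError,
    ScorerParams,
    loso_cv,
    loss,
)
from gaitscore.estimator import make_objective
from gaitscore.io import FEATURE_NAMES
from gaitscore.model import DEFAULT_P, check_constraints
from gaitscore.synth import FeatureGenSpec, generate_features


class TestLoss:
    def test_default_params_r_terms(self):
        """At w = 0 and evenly spaced p: R1 = 0 and R2 = 5 (five unit gaps)."""
        params = ScorerParams(w=np.zeros(3), c=0.0)
        X = np.random.default_rng(0).normal(size=(6, 3))
        y = np.array([0, 0, 1, 1, 2, 2])
        lb = loss(params, X, y)
        assert lb.r1 == 0.0
        assert lb.r2 == pytest.approx(5.0)

    def test_single_subject_hand_assembled(self):
        params = ScorerParams(w=np.zeros(2), c=0.0)
        X = np.array([[1.0, 2.0]])
        y = np.array([0])
        lb = loss(params, X, y, lambda_=0.1, beta=0.005)
        # score of the zero model is the sigmoid value at xhp = 0
        e0 = 5.0 / (1 + np.e**2) - 0.5
        assert lb.e_levels[0] == pytest.approx(e0, abs=1e-9)
        assert lb.total == pytest.approx(e0 + 0.005 * 5.0, abs=1e-9)

    def test_three_row_decomposition(self):
        rng = np.random.default_rng(3)
        params = ScorerParams(w=rng.normal(size=2), c=0.1,
                              p=[0.3, 1.4, 2.6, 3.6])
        X = rng.normal(size=(3, 2))
        y = np.array([0, 1, 1])
        lb = loss(params, X, y, lambda_=0.1, beta=0.005)
        total = (sum(lb.e_levels.values()) / lb.n_levels
                 + 0.1 * lb.r1 + 0.005 * lb.r2)
        assert lb.total == pytest.approx(total, abs=1e-12)
        assert lb.n_levels == 2

    def test_perfect_scorer_zero_error_limit(self, clean_feature_table):
        """With exact labels the error term vanishes and L = lambda R1 + beta R2."""
        table, truth = clean_feature_table
        params = truth["params"]
        X = table[FEATURE_NAMES].to_numpy()
        # construct labels equal to the model's own continuous scores
        from gaitscore.model import score

        y = score(X, params)
        lb = loss(params, X, y)
        assert sum(lb.e_levels.values()) == pytest.approx(0.0, abs=1e-10)
        assert lb.total == pytest.approx(0.1 * lb.r1 + 0.005 * lb.r2, abs=1e-10)

    def test_zero_gap_is_error(self):
        params = ScorerParams.__new__(ScorerParams)
        params.w, params.c = np.zeros(2), 0.0
        params.p = np.array([0.5, 0.5, 2.5, 3.5])
        params.bl, params.bu, params.features = -0.5, 4.5, []
        with pytest.raises(ModelError, match="gap"):
            loss(params, np.zeros((2, 2)), np.array([0, 1]))

    def test_empty_dataset_is_error(self):
        params = ScorerParams(w=np.zeros(2), c=0.0)
        with pytest.raises(InsufficientDataError):
            loss(params, np.zeros((0, 2)), np.zeros(0))


class TestGradient:
    def test_analytic_matches_finite_differences(self):
        table, _ = generate_features(
            FeatureGenSpec(n_per_level={0: 8, 1: 8, 2: 8},
                           noise_band_frac=0.3, seed=11)
        )
        X = table[FEATURE_NAMES].to_numpy()
        X = (X - X.mean(0)) / X.std(0, ddof=1)
        y = table["rated_level"].to_numpy()
        obj, grad, _ = make_objective(X, y)
        rng = np.random.default_rng(1)
        for _ in range(5):
            theta = np.concatenate([
                rng.normal(size=12) * 0.5, [rng.normal() * 0.5],
                np.sort(rng.uniform(-0.2, 4.2, 4)) + np.arange(4) * 0.05,
            ])
            np.testing.assert_allclose(
                grad(theta), approx_fprime(theta, obj, 1e-7),
                rtol=1e-3, atol=1e-5,
            )


class TestFit:
    def test_recovers_levels_from_clean_data(self, clean_feature_table):
        table, truth = clean_feature_table
        X = table[FEATURE_NAMES].to_numpy()
        y = table["rated_level"].to_numpy()
        est = HyperplaneGaitScorer().fit(X, y)
        assert (est.predict(X) == y).mean() >= 0.90
        assert check_constraints(est.params_) == []

    def test_loss_not_above_initial(self, clean_feature_table):
        table, _ = clean_feature_table
        X = table[FEATURE_NAMES].to_numpy()
        y = table["rated_level"].to_numpy()
        est = HyperplaneGaitScorer().fit(X, y)
        init = ScorerParams(w=np.zeros(X.shape[1]), c=0.0,
                            p=np.array(DEFAULT_P))
        assert est.loss_breakdown_.total <= loss(init, X, y).total + 1e-12

    def test_single_informative_feature_dominates(self):
        rng = np.random.default_rng(4)
        n = 60
        y = np.repeat([0, 1, 2], n // 3)
        X = rng.normal(size=(n, 4))
        X[:, 2] = y * 2.0 + rng.normal(scale=0.05, size=n)  # separating feature
        est = HyperplaneGaitScorer().fit(X, y)
        contrib = np.abs(est.coef_) * X.std(axis=0, ddof=1)
        others = np.delete(contrib, 2)
        assert contrib[2] > 5 * others.max()

    def test_huge_lambda_collapses_weights(self, clean_feature_table):
        table, _ = clean_feature_table
        X = table[FEATURE_NAMES].to_numpy()
        y = table["rated_level"].to_numpy()
        est = HyperplaneGaitScorer(lambda_=1e6).fit(X, y)
        assert np.abs(est.coef_ * X.std(axis=0, ddof=1)).max() < 1e-2
        assert np.ptp(est.predict_score(X)) < 0.5  # scores nearly constant

    def test_reproducible(self, clean_feature_table):
        table, _ = clean_feature_table
        X = table[FEATURE_NAMES].to_numpy()
        y = table["rated_level"].to_numpy()
        a = HyperplaneGaitScorer().fit(X, y)
        b = HyperplaneGaitScorer().fit(X, y)
        np.testing.assert_array_equal(a.coef_, b.coef_)
        np.testing.assert_array_equal(a.thresholds_, b.thresholds_)
        assert a.intercept_ == b.intercept_

    def test_needs_two_levels(self):
        with pytest.raises(InsufficientDataError):
            HyperplaneGaitScorer().fit(np.zeros((4, 2)), np.zeros(4))

    def test_boundary_recovery_tightens_with_less_noise(self):
        """Fitted hyperplane crossings approach truth as noise shrinks."""
        errs = {}
        for frac in (0.3, 0.15):
            devs = []
            for seed in (0, 1, 2):
                spec = FeatureGenSpec(n_per_level={0: 40, 1: 40, 2: 40},
                                      noise_band_frac=frac, seed=seed)
                table, truth = generate_features(spec)
                X = table[FEATURE_NAMES].to_numpy()
                Xz = (X - X.mean(0)) / X.std(0, ddof=1)
                y = table["rated_level"].to_numpy()
                est = HyperplaneGaitScorer().fit(Xz, y)
                # compare the two populated boundaries in score space:
                # fraction of points each side must match the truth split
                pred, true_lab = est.predict(Xz), y
                devs.append(np.mean(pred != true_lab))
            errs[frac] = np.mean(devs)
        assert errs[0.15] <= errs[0.3]


class TestLoso:
    def test_fold_count(self, clean_feature_table):
        table, _ = clean_feature_table
        small = table.iloc[[0, 1, 10, 11, 20]]
        res = loso_cv(small, model="mlr")
        assert len(res) == 5

    def test_duplicated_subjects_predict_common_level(self):
        import pandas as pd

        row = {name: v for name, v in zip(FEATURE_NAMES, np.linspace(0.5, 4, 12))}
        rows = []
        for i in range(6):
            r = dict(row)
            r["rated_level"] = 1 if i < 3 else 2
            # two exactly duplicated clusters, separated in one feature
            r["SL"] = 1.0 if i < 3 else 2.0
            rows.append(r)
        table = pd.DataFrame(rows, index=[f"s{i}" for i in range(6)])
        table["group"] = "pd"
        res = loso_cv(table, model="mlr", standardize="none")
        assert (res["pred_level"] == res["true_level"]).all()

    def test_zero_noise_perfect_loso(self, clean_feature_table):
        table, _ = clean_feature_table
        res = loso_cv(table, model="nonlinear")
        assert (res["pred_level"] == res["true_level"]).all()

    def test_too_few_subjects(self, clean_feature_table):
        table, _ = clean_feature_table
        with pytest.raises(InsufficientDataError):
            loso_cv(table.iloc[:2], model="mlr")
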