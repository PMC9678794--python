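"""Adjusted logistic association, BH FDR, standardization, Spearman."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import minimize
from scipy.special import expit

from proteohf.association import (
    adjust_fdr,
    associate_all,
    fit_protein_model,
    spearman_matrix,
    standardize,
    _wald_logit,
)

from conftest import small_config
from proteohf.cohort import generate_study


def bh_step_up(p):
    """Independent brute-force BH: m*p(i)/i on the sorted vector, then a
    running minimum from the largest index."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


class TestStandardize:
    def test_affine_transform(self):
        m = pd.DataFrame({"A": [1.0, 2.0, 3.0]})
        out = standardize(m)
        assert out["A"].mean() == pytest.approx(0.0, abs=1e-12)
        assert out["A"].std(ddof=1) == pytest.approx(1.0)

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        m = pd.DataFrame(rng.normal(5, 3, (40, 3)), columns=list("ABC"))
        once = standardize(m)
        twice = standardize(once)
        np.testing.assert_allclose(once.to_numpy(), twice.to_numpy(), atol=1e-12)

    def test_constant_assay_named_in_error(self):
        m = pd.DataFrame({"A": [1.0, 2.0], "FLAT": [3.0, 3.0]})
        with pytest.raises(ValueError, match="FLAT"):
            standardize(m)


class TestAdjustFdr:
    @pytest.mark.parametrize(
        "p, expected",
        [
            ([0.03], [0.03]),
            ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
            ([0.005, 0.05, 0.5], [0.015, 0.075, 0.5]),
        ],
    )
    def test_hand_computed_step_up(self, p, expected):
        np.testing.assert_allclose(adjust_fdr(p), expected, rtol=1e-12)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=60))
    @settings(max_examples=200, deadline=None)
    def test_matches_brute_force_oracle(self, p):
        np.testing.assert_allclose(adjust_fdr(p), bh_step_up(p), rtol=1e-10, atol=1e-12)

    def test_sorting_by_p_sorts_by_q(self):
        rng = np.random.default_rng(1)
        p = rng.random(50)
        q = adjust_fdr(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            adjust_fdr([0.5, 1.5])
        with pytest.raises(ValueError):
            adjust_fdr([-0.1])


class TestLogisticFit:
    def test_matches_grid_search_mle_on_eight_subjects(self):
        """Intercept+slope logistic fit against a profiled grid search of
        the log-likelihood on an 8-subject toy, to 3 decimals."""
        x = np.array([-1.5, -1.0, -0.5, -0.2, 0.2, 0.6, 1.1, 1.4])
        y = np.array([0.0, 0.0, 1.0, 0.0, 1.0, 0.0, 1.0, 1.0])
        X = np.column_stack([np.ones(8), x])
        coef, _, ok = _wald_logit(y, X)
        assert ok

        def profiled_argmin(b0_grid, b1_grid):
            # nll on the full (b0, b1) grid, intercept profiled out
            eta = b0_grid[:, None, None] + b1_grid[None, :, None] * x
            nll = -(y * eta - np.logaddexp(0.0, eta)).sum(axis=2)
            return b1_grid[int(np.argmin(nll.min(axis=0)))]

        coarse = profiled_argmin(np.arange(-5, 5, 0.01), np.arange(-5, 5, 0.01))
        b1_hat = profiled_argmin(
            np.arange(-5, 5, 0.005),
            np.arange(coarse - 0.02, coarse + 0.02, 0.0002),
        )
        assert coef[1] == pytest.approx(b1_hat, abs=1e-3)

    def test_full_model_matches_independent_likelihood_optimizer(self, small_study):
        """fit_protein_model equals a hand-written negative log-likelihood
        minimized with scipy (BFGS) — an independent route to the MLE."""
        _, cohort, matrix, *_ = small_study
        std = standardize(matrix)
        assay = std.columns[0]
        res = fit_protein_model(cohort, std[assay])
        assert res.converged

        df = cohort.set_index("subject_id").join(std[assay].rename("expr"))
        X = np.column_stack(
            [np.ones(len(df)), df["expr"], df["age"], df["sex"],
             df["surgery"], df["duration"]]
        )
        y = df["is_case"].to_numpy(float)

        def nll(b):
            eta = X @ b
            return -np.sum(y * eta - np.logaddexp(0.0, eta))

        opt = minimize(nll, np.zeros(6), method="BFGS",
                       options={"gtol": 1e-10, "maxiter": 500})
        assert np.log(res.odds_ratio) == pytest.approx(opt.x[1], abs=1e-5)

    def test_null_expression_gives_or_near_one(self):
        cfg = small_config(true_log_or=np.zeros(12), n_below_lod=0,
                           n_cases=150, n_controls=150, population_size=900,
                           seed=3)
        cohort, matrix, *_ = generate_study(cfg)
        out = associate_all(cohort, matrix)
        assert np.abs(np.log(out["odds_ratio"])).mean() < 0.15

    def test_or_equivariance_under_negation(self, small_study):
        _, cohort, matrix, *_ = small_study
        std = standardize(matrix)
        assay = std.columns[0]
        a = fit_protein_model(cohort, std[assay])
        b = fit_protein_model(cohort, -std[assay])
        assert b.odds_ratio == pytest.approx(1.0 / a.odds_ratio, rel=1e-8)
        assert b.ci_low == pytest.approx(1.0 / a.ci_high, rel=1e-8)
        assert b.ci_high == pytest.approx(1.0 / a.ci_low, rel=1e-8)
        assert b.p_value == pytest.approx(a.p_value, rel=1e-8)

    def test_single_class_outcome_rejected(self, small_study):
        _, cohort, matrix, *_ = small_study
        std = standardize(matrix)
        cases_only = cohort[cohort["is_case"] == 1]
        with pytest.raises(ValueError, match="both cases and controls"):
            fit_protein_model(cases_only, std[std.columns[0]])

    def test_result_invariants(self, small_study):
        _, cohort, matrix, meta, _ = small_study
        out = associate_all(cohort, matrix, meta)
        ok = out[out["converged"]]
        assert (ok["ci_low"] <= ok["odds_ratio"]).all()
        assert (ok["odds_ratio"] <= ok["ci_high"]).all()
        assert ((ok["p_value"] >= 0) & (ok["p_value"] <= 1)).all()
        assert (ok["q_value"] >= ok["p_value"] - 1e-12).all()
        assert (ok["odds_ratio"] > 0).all()
        assert (ok["n_used"] == len(cohort)).all()


class TestSpearman:
    def test_self_correlation_is_one(self, small_study):
        _, _, matrix, *_ = small_study
        rho = spearman_matrix(matrix.iloc[:, :4])
        assert np.allclose(np.diag(rho), 1.0)
        np.testing.assert_allclose(rho.to_numpy(), rho.to_numpy().T, atol=1e-12)

    def test_monotone_transform_invariance(self, small_study):
        _, _, matrix, *_ = small_study
        a = matrix.iloc[:, 0]
        df = pd.DataFrame({"a": a, "b": np.exp(a / 2)})
        rho = spearman_matrix(df)
        assert rho.loc["a", "b"] == pytest.approx(1.0)

    def test_tie_handling_matches_hand_ranked_pearson(self):
        """5-point toy with one tie: average ranks, then Pearson on ranks."""
        x = pd.Series([1.0, 2.0, 2.0, 4.0, 5.0])
        y = pd.Series([3.0, 1.0, 4.0, 2.0, 5.0])
        rx = np.array([1.0, 2.5, 2.5, 4.0, 5.0])
        ry = np.array([3.0, 1.0, 4.0, 2.0, 5.0])
        expected = np.corrcoef(rx, ry)[0, 1]
        rho = spearman_matrix(pd.DataFrame({"x": x, "y": y}))
        assert rho.loc["x", "y"] == pytest.approx(expected, rel=1e-12)

    def test_too_few_complete_pairs_is_missing(self):
        df = pd.DataFrame(
            {"x": [1.0, 2.0, np.nan, np.nan, 3.0],
             "y": [1.0, np.nan, 2.0, 3.0, np.nan]}
        )
        rho = spearman_matrix(df)
        assert np.isnan(rho.loc["x", "y"])
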