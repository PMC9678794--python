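"""Per-protein adjusted logistic association with FDR control.

For each retained protein, case status is regressed on the standardized
expression value plus the four matching variables (age, sex, surgery,
follow-up duration) by unconditional logistic regression; the exponent of
the expression coefficient is the standardized odds ratio (sOR, odds
ratio per 1 SD of expression).  p-values are two-sided Wald tests, with
Benjamini-Hochberg adjustment across the protein family.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

MATCHING_COVARIATES = ("age", "sex", "surgery", "duration")


@dataclass
class AssociationResult:
    """Adjusted association of one assay with case status."""

    assay_name: str
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    n_used: int
    converged: bool
    q_value: float = np.nan


def standardize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Scale each assay to mean 0, sample SD 1 over its non-missing values.

    Raises ``ValueError`` naming the assay if one is constant (or has
    fewer than two non-missing values), since its sOR is undefined.
    """
    sd = matrix.std(axis=0, ddof=1)
    bad = sd.index[~(sd > 0)]
    if len(bad):
        raise ValueError(f"constant or empty assay cannot be standardized: {bad[0]!r}")
    return (matrix - matrix.mean(axis=0)) / sd


def _wald_logit(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, np.ndarray, bool]:
    """ML logistic fit; returns (coef, se, converged)."""
    try:
        res = sm.Logit(y, X).fit(disp=0, maxiter=100)
    except Exception:
        return np.full(X.shape[1], np.nan), np.full(X.shape[1], np.nan), False
    se = np.asarray(res.bse, dtype=float)
    converged = bool(res.mle_retvals.get("converged", False)) and np.all(
        np.isfinite(se)
    ) and float(np.max(se)) < 50.0  # huge SE signals separation
    return np.asarray(res.params, dtype=float), se, converged


def fit_protein_model(
    cohort: pd.DataFrame,
    expression: pd.Series,
    extra_covariates: tuple[str, ...] = (),
) -> AssociationResult:
    """Fit is_case ~ expression + age + sex + surgery + duration.

    ``expression`` must be indexed by subject_id and already
    standardized.  Complete-case: subjects with a missing expression
    value are dropped and ``n_used`` records the subjects actually fit.
    Non-convergence or separation is flagged via ``converged`` rather
    than reported as silent numbers.  ``extra_covariates`` names further
    cohort columns to adjust for (off by default).
    """
    covars = MATCHING_COVARIATES + tuple(extra_covariates)
    df = cohort.set_index("subject_id")[["is_case", *covars]].join(
        expression.rename("expr"), how="inner"
    ).dropna()
    y = df["is_case"].to_numpy(dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("outcome must contain both cases and controls")
    X = np.column_stack(
        [np.ones(len(df)), df["expr"].to_numpy(dtype=float)]
        + [df[c].to_numpy(dtype=float) for c in covars]
    )
    coef, se, converged = _wald_logit(y, X)
    b, s = coef[1], se[1]
    z = norm.ppf(0.975)
    if converged:
        p = 2.0 * norm.sf(abs(b) / s)
        result = AssociationResult(
            assay_name=str(expression.name),
            odds_ratio=float(np.exp(b)),
            ci_low=float(np.exp(b - z * s)),
            ci_high=float(np.exp(b + z * s)),
            p_value=float(p),
            n_used=len(df),
            converged=True,
        )
    else:
        result = AssociationResult(
            assay_name=str(expression.name),
            odds_ratio=np.nan, ci_low=np.nan, ci_high=np.nan,
            p_value=np.nan, n_used=len(df), converged=False,
        )
    return result


def adjust_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any(np.isnan(p)) or np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def associate_all(
    cohort: pd.DataFrame,
    matrix: pd.DataFrame,
    assay_meta: pd.DataFrame | None = None,
    extra_covariates: tuple[str, ...] = (),
) -> pd.DataFrame:
    """Standardize, fit every assay, and BH-adjust across converged fits.

    The FDR family is all assays in ``matrix`` whose fit converged
    (q-values of non-converged assays are NaN).  Returns a DataFrame
    with one row per assay: odds_ratio, ci_low, ci_high, p_value,
    q_value, n_used, converged (+ panel if metadata given).
    """
    std = standardize(matrix)
    results = [
        fit_protein_model(cohort, std[assay], extra_covariates=extra_covariates)
        for assay in std.columns
    ]
    out = pd.DataFrame(
        {
            "assay": [r.assay_name for r in results],
            "odds_ratio": [r.odds_ratio for r in results],
            "ci_low": [r.ci_low for r in results],
            "ci_high": [r.ci_high for r in results],
            "p_value": [r.p_value for r in results],
            "n_used": [r.n_used for r in results],
            "converged": [r.converged for r in results],
        }
    )
    out["q_value"] = np.nan
    ok = out["converged"].to_numpy()
    if ok.any():
        out.loc[ok, "q_value"] = adjust_fdr(out.loc[ok, "p_value"].to_numpy())
    if assay_meta is not None:
        out = out.merge(assay_meta[["assay", "panel"]], on="assay", how="left")
        out = out[["assay", "panel", "odds_ratio", "ci_low", "ci_high",
                   "p_value", "q_value", "n_used", "converged"]]
    return out


def spearman_matrix(matrix: pd.DataFrame, min_pairs: int = 3) -> pd.DataFrame:
    """Pairwise Spearman correlations with average ranks for ties.

    Pairwise-complete observations; an entry with fewer than
    ``min_pairs`` complete pairs is NaN.
    """
    rho = matrix.corr(method="spearman", min_periods=min_pairs)
    np.fill_diagonal(rho.values, np.where(matrix.notna().sum() >= 1, 1.0, np.nan))
    return rho
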