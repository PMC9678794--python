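"""Screening for biomarker x obesity-intervention interactions.

Tests, per protein, whether the association with incident HF differs
between the bariatric-surgery and usual-care strata.  The interaction
p-value comes from the product term of a pooled logistic model
(expression, matching covariates, surgery main effect, expression x
surgery); stratum-specific odds ratios come from separate refits within
each stratum, adjusted for the remaining matching variables.  Because
interaction tests are low-powered, flagging uses a lenient screening
alpha of 0.10 rather than a 5% significance level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .association import standardize, _wald_logit

#: matching covariates other than surgery, which is the effect modifier
_STRATUM_COVARIATES = ("age", "sex", "duration")

DEFAULT_INTERACTION_ALPHA = 0.10


class StratumError(ValueError):
    """A surgery stratum lacks cases or controls, or a fit is non-estimable."""


@dataclass
class InteractionResult:
    assay_name: str
    or_no_surgery: float
    p_no_surgery: float
    or_surgery: float
    p_surgery: float
    p_interaction: float
    flagged: bool


def _stratum_effect(df: pd.DataFrame) -> tuple[float, float]:
    """Per-SD OR and Wald p for expression within one surgery stratum."""
    y = df["is_case"].to_numpy(dtype=float)
    X = np.column_stack(
        [np.ones(len(df)), df["expr"].to_numpy(dtype=float)]
        + [df[c].to_numpy(dtype=float) for c in _STRATUM_COVARIATES]
    )
    coef, se, ok = _wald_logit(y, X)
    if not ok:
        raise StratumError("stratified fit did not converge")
    return float(np.exp(coef[1])), float(2.0 * norm.sf(abs(coef[1]) / se[1]))


def fit_interaction_model(
    cohort: pd.DataFrame,
    expression: pd.Series,
    alpha_interaction: float = DEFAULT_INTERACTION_ALPHA,
) -> InteractionResult:
    """Interaction test and stratum effects for one standardized assay.

    Raises :class:`StratumError` if either surgery stratum lacks both
    outcome classes or any fit is non-estimable, rather than returning
    silent numbers.
    """
    if not 0.0 < alpha_interaction < 1.0:
        raise ValueError("alpha_interaction must be in (0, 1)")
    df = cohort.set_index("subject_id")[
        ["is_case", "surgery", *_STRATUM_COVARIATES]
    ].join(expression.rename("expr"), how="inner").dropna()

    for s in (0, 1):
        stratum_y = df.loc[df["surgery"] == s, "is_case"]
        if stratum_y.nunique() < 2:
            raise StratumError(
                f"surgery stratum {s} lacks cases or controls"
            )

    y = df["is_case"].to_numpy(dtype=float)
    expr = df["expr"].to_numpy(dtype=float)
    surg = df["surgery"].to_numpy(dtype=float)
    X = np.column_stack(
        [np.ones(len(df)), expr, surg, expr * surg]
        + [df[c].to_numpy(dtype=float) for c in _STRATUM_COVARIATES]
    )
    coef, se, ok = _wald_logit(y, X)
    if not ok:
        raise StratumError("pooled interaction model did not converge")
    p_int = float(2.0 * norm.sf(abs(coef[3]) / se[3]))

    or0, p0 = _stratum_effect(df[df["surgery"] == 0])
    or1, p1 = _stratum_effect(df[df["surgery"] == 1])

    return InteractionResult(
        assay_name=str(expression.name),
        or_no_surgery=or0, p_no_surgery=p0,
        or_surgery=or1, p_surgery=p1,
        p_interaction=p_int,
        flagged=bool(p_int < alpha_interaction),
    )


def interaction_screen(
    cohort: pd.DataFrame,
    matrix: pd.DataFrame,
    assays: list[str] | None = None,
    alpha_interaction: float = DEFAULT_INTERACTION_ALPHA,
) -> pd.DataFrame:
    """Run the interaction screen over ``assays`` (default: all).

    Non-estimable assays are reported with NaN effects and
    ``estimable = False`` instead of being dropped silently.
    """
    std = standardize(matrix if assays is None else matrix[assays])
    rows = []
    for assay in std.columns:
        try:
            r = fit_interaction_model(cohort, std[assay], alpha_interaction)
            rows.append(
                {
                    "assay": assay,
                    "or_no_surgery": r.or_no_surgery,
                    "p_no_surgery": r.p_no_surgery,
                    "or_surgery": r.or_surgery,
                    "p_surgery": r.p_surgery,
                    "p_interaction": r.p_interaction,
                    "flagged": r.flagged,
                    "estimable": True,
                }
            )
        except StratumError:
            rows.append(
                {
                    "assay": assay,
                    "or_no_surgery": np.nan, "p_no_surgery": np.nan,
                    "or_surgery": np.nan, "p_surgery": np.nan,
                    "p_interaction": np.nan, "flagged": False,
                    "estimable": False,
                }
            )
    return pd.DataFrame(rows)
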