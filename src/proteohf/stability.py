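"""Bootstrap stability selection: rank proteins by how often they stay
FDR-significant across resamples of the cohort.

For each bootstrap resample (matched pairs drawn with replacement by
default, preserving the design's case-control balance), every protein's
adjusted logistic model is refit and Benjamini-Hochberg FDR is re-applied
across the protein family *within that resample*; a protein is "selected"
in the resample if its q-value falls below the FDR level.  The selection
proportion over resamples ranks the proteins, and the published tier
semantics classify them: selected >=80% of the time -> major mechanistic
importance; 50-80% (inclusive at 0.50, exclusive at 0.80) -> potential
significance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .association import standardize, adjust_fdr, _wald_logit, MATCHING_COVARIATES

logger = logging.getLogger(__name__)

_MAX_REDRAWS = 100


@dataclass
class StabilityConfig:
    n_bootstrap: int = 5000
    fdr_level: float = 0.05
    tier_major: float = 0.80
    tier_potential: float = 0.50
    resample_unit: str = "pair"  # "pair" or "subject"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_bootstrap < 1:
            raise ValueError("n_bootstrap must be positive")
        if not 0.0 < self.fdr_level < 1.0:
            raise ValueError("fdr_level must be in (0, 1)")
        if not 0.5 <= self.tier_major <= 1.0:
            raise ValueError("tier_major must be in [0.5, 1]")
        if not 0.0 <= self.tier_potential < self.tier_major:
            raise ValueError("tier_potential must be below tier_major")
        if self.resample_unit not in ("pair", "subject"):
            raise ValueError("resample_unit must be 'pair' or 'subject'")


def classify_tier(selection_proportion: float, config: StabilityConfig) -> str:
    """Tier label for a selection proportion: major / potential / none."""
    if not 0.0 <= selection_proportion <= 1.0:
        raise ValueError("selection proportion must lie in [0, 1]")
    if selection_proportion >= config.tier_major:
        return "major"
    if selection_proportion >= config.tier_potential:
        return "potential"
    return "none"


def _resample_units(cohort: pd.DataFrame, unit: str) -> list[np.ndarray]:
    """Row-index groups drawn as a block in each resample."""
    if unit == "subject":
        return [np.array([i]) for i in range(len(cohort))]
    groups = cohort.groupby("pair_id", sort=True).indices
    return [np.asarray(v) for _, v in sorted(groups.items())]


def bootstrap_selection(
    cohort: pd.DataFrame,
    matrix: pd.DataFrame,
    config: StabilityConfig,
) -> pd.DataFrame:
    """Selection proportion and tier per assay over bootstrap resamples.

    Expression is standardized once on the full cohort, so a protein's
    sOR scale is fixed across resamples.  A resample whose outcome is
    single-class is redrawn (up to 100 times, then a hard error).  A
    protein whose fit fails to converge in a resample is excluded both
    from that resample's FDR family and from its own denominator
    (``n_effective_bootstraps`` counts convergent resamples).

    Per-bootstrap RNG substreams are derived from ``(seed, bootstrap
    index)``, so proportions do not depend on execution order.
    """
    std = standardize(matrix)
    subj = cohort.set_index("subject_id")
    std = std.loc[subj.index]  # align rows

    y_full = subj["is_case"].to_numpy(dtype=float)
    covar = np.column_stack(
        [subj[c].to_numpy(dtype=float) for c in MATCHING_COVARIATES]
    )
    expr = std.to_numpy(dtype=float)
    n, p = expr.shape
    assays = list(std.columns)
    units = _resample_units(cohort.reset_index(drop=True), config.resample_unit)

    selected = np.zeros(p, dtype=np.int64)
    effective = np.zeros(p, dtype=np.int64)
    n_redrawn = 0

    for b in range(config.n_bootstrap):
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=config.seed, spawn_key=(b,))
        )
        for attempt in range(_MAX_REDRAWS + 1):
            pick = rng.integers(0, len(units), size=len(units))
            rows = np.concatenate([units[u] for u in pick])
            y = y_full[rows]
            if 0.0 < y.mean() < 1.0:
                break
            n_redrawn += 1
        else:
            raise RuntimeError(
                "could not draw a two-class bootstrap resample in "
                f"{_MAX_REDRAWS} attempts"
            )
        Xcov = covar[rows]
        ones = np.ones(len(rows))
        pvals = np.full(p, np.nan)
        for j in range(p):
            X = np.column_stack([ones, expr[rows, j], Xcov])
            coefs, ses, ok = _wald_logit(y, X)
            if ok:
                pvals[j] = 2.0 * norm.sf(abs(coefs[1]) / ses[1])
        ok_mask = np.isfinite(pvals)
        effective += ok_mask
        if ok_mask.any():
            q = adjust_fdr(pvals[ok_mask])
            sel = np.zeros(p, dtype=bool)
            sel[np.flatnonzero(ok_mask)[q < config.fdr_level]] = True
            selected += sel
        logger.debug("bootstrap %d/%d done", b + 1, config.n_bootstrap)

    if n_redrawn:
        logger.info("redrew %d degenerate single-class resample(s)", n_redrawn)

    with np.errstate(invalid="ignore"):
        proportion = np.where(effective > 0, selected / np.maximum(effective, 1), np.nan)
    out = pd.DataFrame(
        {
            "assay": assays,
            "selection_proportion": proportion,
            "n_effective_bootstraps": effective,
        }
    )
    out["tier"] = [
        classify_tier(v, config) if np.isfinite(v) else "none"
        for v in out["selection_proportion"]
    ]
    return out[["assay", "selection_proportion", "tier", "n_effective_bootstraps"]]
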