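"""Published baseline characteristics of the motivating cohort.

These are the printed mean +- SD summaries and category counts for the
411 incident-HF cases and 410 matched controls of the obesity cohort
that motivates this pipeline.  They serve as inputs to the descriptive
comparisons in :mod:`proteohf.inference` (t-tests are computable from
summary statistics alone) and as realism anchors for the synthetic
cohort generator.
"""

from __future__ import annotations

import numpy as np

from .inference import SummaryRow

N_CASES = 411
N_CONTROLS = 410

#: variable -> (mean_cases, sd_cases, mean_controls, sd_controls)
BASELINE_CONTINUOUS: dict[str, tuple[float, float, float, float]] = {
    "age": (51.0, 6.0, 51.0, 6.0),
    "duration": (15.6, 5.9, 15.6, 5.9),
    "bmi": (41.0, 5.0, 40.1, 4.6),
    "sbp": (145.9, 19.0, 142.6, 18.3),
    "dbp": (89.5, 11.3, 89.1, 10.9),
    "heart_rate": (71.8, 13.8, 69.3, 12.6),
    "creatinine": (70.6, 11.0, 70.9, 9.6),
    "chol": (5.95, 1.12, 5.83, 1.11),
    "hdl": (1.31, 0.33, 1.38, 0.36),
    "tg": (2.41, 1.71, 2.07, 1.53),
    "glucose": (5.45, 2.19, 4.99, 1.73),
}

#: variable -> 2 x k counts, rows (cases, controls)
BASELINE_CATEGORICAL: dict[str, np.ndarray] = {
    "diabetes": np.array([[92, 319], [64, 346]]),
    # columns: former, current, never smoker
    "smoking": np.array([[179, 104, 128], [177, 73, 160]]),
}


def summary_row(variable: str) -> SummaryRow:
    """The printed case/control summary of one continuous variable."""
    m1, s1, m2, s2 = BASELINE_CONTINUOUS[variable]
    return SummaryRow(variable, m1, s1, N_CASES, m2, s2, N_CONTROLS)
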