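import numpy as np
import pandas as pd
import pytest

from proteohf.cohort import GeneratorConfig, generate_study


def small_config(**kw) -> GeneratorConfig:
    """A scaled-down study: 60 matched pairs, 12 assays, 2 below LOD."""
    beta = np.zeros(12)
    beta[0] = np.log(2.5)
    beta[1] = np.log(0.5)
    defaults = dict(
        n_cases=60,
        n_controls=60,
        population_size=500,
        n_proteins=12,
        n_below_lod=2,
        true_log_or=beta,
        correlation_block_spec=((4, 0.3),),
        seed=7,
    )
    defaults.update(kw)
    return GeneratorConfig(**defaults)


@pytest.fixture(scope="session")
def small_study():
    cfg = small_config()
    cohort, matrix, meta, truth = generate_study(cfg)
    return cfg, cohort, matrix, meta, truth


@pytest.fixture(scope="session")
def default_study():
    """The full-size synthetic study (411 cases / 410 controls, 184 assays)."""
    cfg = GeneratorConfig()
    cohort, matrix, meta, truth = generate_study(cfg)
    return cfg, cohort, matrix, meta, truth


def toy_population() -> pd.DataFrame:
    """Ten subjects with hand-set event/censoring times for enumeration."""
    df = pd.DataFrame(
        {
            "person_id": range(10),
            "age": [50, 51, 49, 50, 52, 50, 48, 50, 51, 50],
            "sex": [1, 1, 1, 1, 0, 0, 0, 0, 1, 1],
            "surgery": [0, 0, 0, 0, 0, 0, 0, 0, 0, 0],
            "is_case": [1, 0, 0, 1, 1, 0, 0, 0, 1, 0],
            "event_time": [5.0, np.inf, np.inf, 8.0, 4.0, np.inf, np.inf,
                           np.inf, 12.0, np.inf],
            "censor_time": [20, 6.0, 10.0, 20, 20, 3.0, 9.0, 15.0, 20, 11.0],
        }
    )
    df["at_risk_until"] = np.where(df["is_case"] == 1, df["event_time"],
                                   df["censor_time"])
    for col in ("bmi", "sbp", "dbp", "heart_rate", "creatinine", "chol",
                "hdl", "tg", "glucose"):
        df[col] = 1.0
    df["diabetes"] = 0
    df["smoking"] = "never"
    return df
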