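"""Synthetic nested matched case-control cohort with planted protein effects.

Emulates the design of a matched case-control study nested in an obesity
treatment cohort: subjects are followed for incident heart failure (HF),
each incident case is matched to one control drawn from the risk set
(subjects still event-free at the case's event time), and plasma protein
expression is attached on a log2 scale with known per-protein effects so
that downstream estimates can be checked against ground truth.

The generator's defaults mirror the motivating study: 411 incident-HF
cases matched 1:1 on age, sex, bariatric surgery and follow-up time; one
control lost to a missing plasma sample (410 controls, 821 subjects in
total); 184 assays on two 92-plex panels of which six are engineered to
fall mostly below their limit of detection; planted standardized odds
ratios of the magnitude reported for the study's top biomarkers; and a
surgery-dependent (interaction) effect for three proteins.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq
from scipy.special import expit  # noqa: F401  (re-exported for simulation helpers)

logger = logging.getLogger(__name__)

#: RNG substream labels: the master seed spawns one independent stream per
#: stage so a stage can be regenerated without re-running the others.
_SUBSTREAMS = {"population": 0, "matching": 1, "proteins": 2}

#: Standardized odds ratios of the 32 biomarkers that survived FDR control
#: in the motivating study, used (on the log scale) as the default planted
#: global effects.  Order: strongest bootstrap support first.
TOP_BIOMARKER_ORS: tuple[float, ...] = (
    2.85, 2.29, 3.26, 1.53, 1.97, 0.64, 1.53, 3.37, 1.77, 1.47,
    1.79, 2.19, 1.37, 2.02, 2.01, 1.36, 1.80, 1.26, 1.35, 1.20,
    1.25, 0.64, 1.77, 1.69, 1.82, 1.46, 1.65, 1.65, 1.54, 1.45,
    1.61, 1.99,
)

#: Default surgery-dependent effects: (assay index into the planted list,
#: stratum OR without surgery, stratum OR with surgery).  Sized after the
#: three proteins whose HF association was confined to the no-surgery
#: stratum (C1QTNF1-, FGF21- and CST3-like magnitudes).
INTERACTION_PROTEINS: tuple[tuple[int, float, float], ...] = (
    (9, 1.80, 1.16),
    (19, 1.39, 1.02),
    (23, 2.26, 1.14),
)


class ConfigError(ValueError):
    """A generator configuration violates one of its invariants."""


@dataclass
class GeneratorConfig:
    """Study-design parameters of the synthetic cohort.

    ``true_log_or`` is the planted log odds ratio per 1 SD of expression
    (the effect in the surgery stratum when an interaction is planted);
    ``interaction_log_or`` is the *additional* log OR applied in the
    no-surgery stratum only.  Both default to ``None``, which expands to
    the study-sized defaults (32 planted effects, 3 interactions).
    """

    n_cases: int = 411
    n_controls: int = 410
    population_size: int = 4037
    n_proteins: int = 184
    n_below_lod: int = 6
    true_log_or: np.ndarray | None = None
    interaction_log_or: np.ndarray | None = None
    correlation_block_spec: tuple[tuple[int, float], ...] = ((8, 0.35),)
    surgery_fraction: float = 0.42
    age_caliper: float = 2.0
    lod_quantile: float = 0.02
    seed: int = 20260924

    def __post_init__(self) -> None:
        if self.n_cases <= 0:
            raise ConfigError("n_cases must be positive")
        if not 0 <= self.n_controls <= self.n_cases:
            raise ConfigError("n_controls must be in [0, n_cases]")
        if self.population_size < 2 * self.n_cases:
            raise ConfigError("population_size must be at least 2 * n_cases")
        if self.n_proteins <= 0:
            raise ConfigError("n_proteins must be positive")
        if not 0 <= self.n_below_lod <= self.n_proteins:
            raise ConfigError("n_below_lod must be in [0, n_proteins]")
        if not 0.0 < self.surgery_fraction < 1.0:
            raise ConfigError("surgery_fraction must be in (0, 1)")
        if not 0.0 < self.lod_quantile < 1.0:
            raise ConfigError("lod_quantile must be in (0, 1)")
        if self.age_caliper <= 0:
            raise ConfigError("age_caliper must be positive")
        for size, rho in self.correlation_block_spec:
            if size < 1:
                raise ConfigError("correlation block size must be >= 1")
            if not -1.0 <= rho < 1.0:
                raise ConfigError("block correlation must be in [-1, 1)")
        if self.true_log_or is None:
            beta = np.zeros(self.n_proteins)
            k = min(len(TOP_BIOMARKER_ORS), self.n_proteins)
            beta[:k] = np.log(TOP_BIOMARKER_ORS[:k])
            delta = np.zeros(self.n_proteins)
            for idx, or_nosurg, or_surg in INTERACTION_PROTEINS:
                if idx < self.n_proteins:
                    beta[idx] = math.log(or_surg)
                    delta[idx] = math.log(or_nosurg) - math.log(or_surg)
            self.true_log_or = beta
            if self.interaction_log_or is None:
                self.interaction_log_or = delta
        else:
            self.true_log_or = np.asarray(self.true_log_or, dtype=float)
        if self.interaction_log_or is None:
            self.interaction_log_or = np.zeros(self.n_proteins)
        else:
            self.interaction_log_or = np.asarray(self.interaction_log_or, dtype=float)
        if len(self.true_log_or) != self.n_proteins:
            raise ConfigError("true_log_or must have length n_proteins")
        if len(self.interaction_log_or) != self.n_proteins:
            raise ConfigError("interaction_log_or must have length n_proteins")

    def rng(self, stage: str) -> np.random.Generator:
        """Named RNG substream for one generation stage."""
        return np.random.default_rng(
            np.random.SeedSequence(entropy=self.seed, spawn_key=(_SUBSTREAMS[stage],))
        )

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["true_log_or"] = [float(v) for v in self.true_log_or]
        d["interaction_log_or"] = [float(v) for v in self.interaction_log_or]
        d["correlation_block_spec"] = [list(b) for b in self.correlation_block_spec]
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        d["correlation_block_spec"] = tuple(
            (int(s), float(r)) for s, r in d["correlation_block_spec"]
        )
        for key in ("true_log_or", "interaction_log_or"):
            if d.get(key) is not None:
                d[key] = np.asarray(d[key], dtype=float)
        return cls(**d)


# log-hazard-ratio per unit of each (uncentered) baseline covariate; these
# induce the case-control imbalances of a worse cardiometabolic profile in
# cases without any treatment effect of surgery itself.
_HAZARD_COEF = {
    "age": 0.040,
    "sex": 0.60,       # male
    "bmi": 0.035,
    "sbp": 0.008,
    "heart_rate": 0.012,
    "tg": 0.080,
    "hdl": -0.30,
    "glucose": 0.060,
    "diabetes": 0.25,
    "smoking_current": 0.30,
}

SMOKING_LEVELS = ("never", "former", "current")


def generate_population(config: GeneratorConfig) -> pd.DataFrame:
    """Simulate the source cohort with baseline covariates and event times.

    Event times are exponential with a log-linear covariate hazard;
    censoring is administrative (uniform follow-up).  The baseline hazard
    is calibrated so the expected number of incident events slightly
    exceeds ``n_cases``; the realized case series is then thinned at
    random to exactly ``n_cases`` (a fixed-size case series, as in a
    nested study that enrols a predetermined number of cases).
    """
    rng = config.rng("population")
    n = config.population_size

    pop = pd.DataFrame(
        {
            "person_id": np.arange(n),
            "age": np.clip(rng.normal(48.0, 6.0, n), 25.0, 70.0),
            "sex": (rng.random(n) < 0.30).astype(int),  # 1 = male
            "surgery": (rng.random(n) < config.surgery_fraction).astype(int),
            "bmi": np.clip(rng.normal(40.5, 4.8, n), 30.0, 65.0),
            "sbp": np.clip(rng.normal(144.0, 19.0, n), 90.0, 230.0),
            "dbp": np.clip(rng.normal(89.0, 11.0, n), 55.0, 140.0),
            "heart_rate": np.clip(rng.normal(70.0, 13.0, n), 40.0, 130.0),
            "creatinine": np.clip(rng.normal(70.5, 10.0, n), 35.0, 130.0),
            "chol": np.clip(rng.normal(5.9, 1.1, n), 2.5, 11.0),
            "hdl": np.clip(rng.normal(1.35, 0.35, n), 0.5, 3.0),
            "tg": np.clip(rng.lognormal(math.log(1.9), 0.55, n), 0.3, 15.0),
            "diabetes": (rng.random(n) < 0.19).astype(int),
        }
    )
    pop["glucose"] = np.clip(
        np.where(
            pop["diabetes"] == 1,
            rng.normal(8.0, 2.5, n),
            rng.normal(5.0, 0.8, n),
        ),
        3.0,
        25.0,
    )
    pop["smoking"] = rng.choice(SMOKING_LEVELS, size=n, p=(0.36, 0.43, 0.21))
    pop["censor_time"] = rng.uniform(6.0, 26.0, n)

    lin = np.zeros(n)
    for cov, coef in _HAZARD_COEF.items():
        if cov == "smoking_current":
            x = (pop["smoking"] == "current").astype(float)
        else:
            x = pop[cov].astype(float)
        lin += coef * (x - x.mean())
    rel_hazard = np.exp(lin)

    # calibrate the baseline hazard with a margin above n_cases large
    # enough (in absolute and in sqrt-n terms) that a realized shortfall
    # below n_cases is vanishingly unlikely
    target = config.n_cases + max(0.15 * config.n_cases, 4.0 * math.sqrt(config.n_cases))

    def expected_events(lam0: float) -> float:
        return float(np.sum(-np.expm1(-lam0 * rel_hazard * pop["censor_time"])))

    lam0 = brentq(lambda v: expected_events(v) - target, 1e-8, 10.0)

    event_time = rng.exponential(1.0 / (lam0 * rel_hazard))
    is_event = event_time < pop["censor_time"].to_numpy()
    n_events = int(is_event.sum())
    if n_events < config.n_cases:
        raise RuntimeError(
            f"simulated only {n_events} events; need {config.n_cases} "
            "(population too small for the requested case count)"
        )
    keep = rng.choice(np.flatnonzero(is_event), size=config.n_cases, replace=False)
    is_case = np.zeros(n, dtype=bool)
    is_case[keep] = True

    pop["event_time"] = np.where(is_case, event_time, np.inf)
    pop["is_case"] = is_case.astype(int)
    # time at risk: event time for cases, censoring time otherwise
    pop["at_risk_until"] = np.where(is_case, event_time, pop["censor_time"])
    return pop


_COVARIATE_COLS = [
    "age", "sex", "surgery", "bmi", "sbp", "dbp", "heart_rate",
    "creatinine", "chol", "hdl", "tg", "glucose", "diabetes", "smoking",
]


def risk_set_match(population: pd.DataFrame, config: GeneratorConfig) -> pd.DataFrame:
    """Match each case to one control from its risk set.

    Eligibility at a case's event time t: same sex, same surgery group,
    age within ``config.age_caliper`` years, still event-free at t
    (censored no earlier than t, or a later case — incidence-density
    sampling), and not already used as a control.  Among eligible
    subjects the nearest in age is taken, ties broken by person id, so
    matching is deterministic given the population.  Controls inherit
    the matched case's event time as their ``duration`` covariate.

    ``n_cases - n_controls`` matched controls are then discarded at
    random (the missing-plasma-sample mechanism of the motivating
    study), leaving those cases unmatched.
    """
    rng = config.rng("matching")
    cases = population[population["is_case"] == 1].sort_values("event_time")
    pool = population  # cases may serve as controls before their own event

    used = np.zeros(len(population), dtype=bool)
    pos = {pid: i for i, pid in enumerate(population["person_id"])}
    age = population["age"].to_numpy()
    sex = population["sex"].to_numpy()
    surgery = population["surgery"].to_numpy()
    at_risk_until = population["at_risk_until"].to_numpy()
    person_ids = population["person_id"].to_numpy()

    rows: list[dict] = []
    pair_id = 0
    n_unmatched = 0
    for case in cases.itertuples():
        t = case.event_time
        i = pos[case.person_id]
        eligible = (
            (~used)
            & (at_risk_until >= t)
            & (sex == case.sex)
            & (surgery == case.surgery)
            & (np.abs(age - case.age) <= config.age_caliper)
        )
        eligible[i] = False
        idx = np.flatnonzero(eligible)
        control_i: int | None = None
        if idx.size:
            control_i = int(idx[np.argmin(np.abs(age[idx] - case.age))])

        rows.append(
            {
                "person_id": case.person_id,
                "pair_id": pair_id,
                "is_case": 1,
                "duration": t,
                **{c: getattr(case, c) for c in _COVARIATE_COLS},
            }
        )
        if control_i is None:
            n_unmatched += 1
            logger.warning(
                "no eligible control for case person_id=%s at t=%.2f; "
                "case retained unmatched", case.person_id, t,
            )
        else:
            used[control_i] = True
            crow = pool.iloc[control_i]
            rows.append(
                {
                    "person_id": int(person_ids[control_i]),
                    "pair_id": pair_id,
                    "is_case": 0,
                    "duration": t,  # inherits the case's time to incident HF
                    **{c: crow[c] for c in _COVARIATE_COLS},
                }
            )
        pair_id += 1

    cohort = pd.DataFrame(rows)

    # missing plasma samples: drop controls at random until n_controls remain
    n_drop = (config.n_cases - n_unmatched) - config.n_controls
    if n_drop > 0:
        ctrl_idx = cohort.index[cohort["is_case"] == 0].to_numpy()
        drop = rng.choice(ctrl_idx, size=n_drop, replace=False)
        logger.info("dropping %d matched control(s) to emulate missing plasma", n_drop)
        cohort = cohort.drop(index=drop).reset_index(drop=True)

    n_case = int((cohort["is_case"] == 1).sum())
    cohort["subject_id"] = [
        f"{'HF' if c else 'CT'}{k:04d}"
        for c, k in zip(cohort["is_case"], range(1, len(cohort) + 1))
    ]
    cols = ["subject_id", "person_id", "pair_id", "is_case", "duration"] + _COVARIATE_COLS
    logger.info(
        "matched cohort: %d cases, %d controls (%d unmatched case(s))",
        n_case, len(cohort) - n_case, n_unmatched,
    )
    return cohort[cols]


def _block_noise(rng: np.random.Generator, n_subjects: int, n_proteins: int,
                 block_spec: tuple[tuple[int, float], ...]) -> np.ndarray:
    """Unit-variance Gaussian noise with block-exchangeable correlation."""
    noise = np.empty((n_subjects, n_proteins))
    j = 0
    spec_i = 0
    while j < n_proteins:
        size, rho = block_spec[spec_i % len(block_spec)]
        size = min(size, n_proteins - j)
        if rho > 0:
            shared = rng.standard_normal((n_subjects, 1))
            eps = rng.standard_normal((n_subjects, size))
            noise[:, j:j + size] = math.sqrt(rho) * shared + math.sqrt(1 - rho) * eps
        else:
            noise[:, j:j + size] = rng.standard_normal((n_subjects, size))
        j += size
        spec_i += 1
    return noise


def attach_proteins(
    cohort: pd.DataFrame, config: GeneratorConfig
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Attach log2-scale protein expression with planted effects.

    Expression is unit-SD Gaussian noise (block-correlated per
    ``correlation_block_spec``) around a per-assay baseline level.  A
    protein with planted log OR b has its case distribution shifted by b:
    if controls are N(mu, 1) and cases N(mu + b, 1), the likelihood ratio
    is log-linear in expression with slope exactly b, so the logistic
    per-SD log OR equals the planted value.  Interaction proteins get the
    additional no-surgery shift only in no-surgery cases.

    ``n_below_lod`` effect-free assays are given a detection limit at
    their 90th percentile so that >80% of values fall strictly below it;
    all other assays get their LOD at ``config.lod_quantile``.

    Returns ``(matrix, assay_meta, truth)``.
    """
    rng = config.rng("proteins")
    n_sub = len(cohort)
    p = config.n_proteins

    width = max(3, len(str(p)))
    assays = [f"PROT{j + 1:0{width}d}" for j in range(p)]
    half = (p + 1) // 2
    panels = ["CVD-II"] * half + ["CM"] * (p - half)

    baseline = rng.uniform(2.0, 10.0, p)
    values = _block_noise(rng, n_sub, p, config.correlation_block_spec)

    is_case = cohort["is_case"].to_numpy() == 1
    no_surgery = cohort["surgery"].to_numpy() == 0
    beta = config.true_log_or
    delta = config.interaction_log_or
    values[is_case] += beta
    values[is_case & no_surgery] += delta
    values += baseline

    # below-LOD assays are drawn from the effect-free proteins
    null_assays = np.flatnonzero((beta == 0) & (delta == 0))
    if null_assays.size < config.n_below_lod:
        raise ConfigError(
            "not enough effect-free proteins to host the below-LOD assays"
        )
    below = rng.choice(null_assays, size=config.n_below_lod, replace=False)
    below_flag = np.zeros(p, dtype=bool)
    below_flag[below] = True

    lod = np.quantile(values, config.lod_quantile, axis=0)
    lod[below_flag] = np.quantile(values[:, below_flag], 0.90, axis=0)

    matrix = pd.DataFrame(values, index=cohort["subject_id"].to_numpy(), columns=assays)
    matrix.index.name = "subject_id"
    meta = pd.DataFrame({"assay": assays, "panel": panels, "lod": lod})
    truth = pd.DataFrame(
        {
            "assay": assays,
            "true_log_or": beta,
            "interaction_log_or": delta,
            "below_lod": below_flag.astype(int),
        }
    )
    return matrix, meta, truth


def generate_study(
    config: GeneratorConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Run all three stages: population, matching, proteins.

    Returns ``(cohort, matrix, assay_meta, truth)``.
    """
    config = config or GeneratorConfig()
    population = generate_population(config)
    cohort = risk_set_match(population, config)
    matrix, meta, truth = attach_proteins(cohort, config)
    return cohort, matrix, meta, truth


def write_study(outdir, cohort, matrix, meta, truth, config=None) -> dict:
    """Write the study tables as CSV; returns {name: path}."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "subjects": outdir / "subjects.csv",
        "matrix": outdir / "protein_matrix.csv",
        "assay_meta": outdir / "assay_meta.csv",
        "truth": outdir / "truth.csv",
    }
    cohort.to_csv(paths["subjects"], index=False, float_format="%.10g")
    matrix.to_csv(paths["matrix"], float_format="%.10g")
    meta.to_csv(paths["assay_meta"], index=False, float_format="%.10g")
    truth.to_csv(paths["truth"], index=False, float_format="%.10g")
    if config is not None:
        paths["config"] = outdir / "generator_config.yaml"
        config.to_yaml(paths["config"])
    return {k: str(v) for k, v in paths.items()}
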