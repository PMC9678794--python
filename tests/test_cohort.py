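"""Synthetic cohort generator: design counts, risk-set validity, truth."""

import numpy as np
import pandas as pd
import pytest

from proteohf.cohort import (
    ConfigError,
    GeneratorConfig,
    attach_proteins,
    generate_population,
    generate_study,
    risk_set_match,
    write_study,
)
from proteohf.studyio import filter_by_lod

from conftest import small_config, toy_population


class TestDesignCounts:
    def test_default_config_reproduces_study_size(self, default_study):
        """411 cases, 410 controls, 821 subjects, 184 assays on two panels."""
        _, cohort, matrix, meta, truth = default_study
        assert (cohort["is_case"] == 1).sum() == 411
        assert (cohort["is_case"] == 0).sum() == 410
        assert len(cohort) == 821
        assert matrix.shape == (821, 184)
        assert set(meta["panel"]) == {"CVD-II", "CM"}
        assert truth["below_lod"].sum() == 6

    def test_surgery_prevalence_near_configured_fraction(self, default_study):
        _, cohort, *_ = default_study
        assert cohort["surgery"].mean() == pytest.approx(0.42, abs=0.06)

    def test_cases_and_controls_balanced_on_matching_variables(self, default_study):
        """Matching makes case/control age indistinguishable (t-test p ~ 1)."""
        from scipy.stats import ttest_ind

        _, cohort, *_ = default_study
        cases = cohort[cohort["is_case"] == 1]
        ctrls = cohort[cohort["is_case"] == 0]
        p = ttest_ind(cases["age"], ctrls["age"], equal_var=False).pvalue
        assert p > 0.3
        # sex and surgery are matched exactly within pairs
        paired = cohort.groupby("pair_id").filter(lambda g: len(g) == 2)
        for col in ("sex", "surgery"):
            assert (paired.groupby("pair_id")[col].nunique() == 1).all()


class TestRiskSetValidity:
    @pytest.mark.parametrize("seed", [7, 8, 9])
    def test_every_control_event_free_at_case_event_time(self, seed):
        cfg = small_config(seed=seed)
        population = generate_population(cfg)
        cohort = risk_set_match(population, cfg)
        at_risk = population.set_index("person_id")["at_risk_until"]
        ctrls = cohort[cohort["is_case"] == 0]
        assert (at_risk.loc[ctrls["person_id"]].to_numpy()
                >= ctrls["duration"].to_numpy()).all()

    def test_controls_inherit_case_duration(self, small_study):
        _, cohort, *_ = small_study
        paired = cohort.groupby("pair_id").filter(lambda g: len(g) == 2)
        assert (paired.groupby("pair_id")["duration"].nunique() == 1).all()

    def test_matches_brute_force_enumeration_on_toy(self):
        """On a 10-subject toy, each match is the nearest-age member of the
        hand-enumerated risk set, processed in event-time order."""
        pop = toy_population()
        cfg = GeneratorConfig(n_cases=4, n_controls=4, population_size=10,
                              n_proteins=1, n_below_lod=0,
                              true_log_or=np.zeros(1), seed=0)
        cohort = risk_set_match(pop, cfg)

        used: set[int] = set()
        expected: dict[int, int | None] = {}
        for case in pop[pop["is_case"] == 1].sort_values("event_time").itertuples():
            eligible = [
                r.person_id
                for r in pop.itertuples()
                if r.person_id != case.person_id
                and r.person_id not in used
                and r.at_risk_until >= case.event_time
                and r.sex == case.sex
                and r.surgery == case.surgery
                and abs(r.age - case.age) <= cfg.age_caliper
            ]
            if eligible:
                ages = pop.set_index("person_id")["age"]
                pick = min(eligible, key=lambda pid: (abs(ages[pid] - case.age), pid))
                used.add(pick)
                expected[case.person_id] = pick
            else:
                expected[case.person_id] = None

        for case_pid, ctrl_pid in expected.items():
            pair = cohort.loc[
                (cohort["person_id"] == case_pid) & (cohort["is_case"] == 1),
                "pair_id",
            ].iloc[0]
            ctrl = cohort[(cohort["pair_id"] == pair) & (cohort["is_case"] == 0)]
            if ctrl_pid is None:
                assert ctrl.empty
            else:
                assert ctrl["person_id"].iloc[0] == ctrl_pid

    def test_future_case_may_serve_as_control_first(self):
        """Subject 3 (case at t=8) is event-free at t=5 and is the nearest-age
        match for case 0, so it appears once as control and once as case."""
        pop = toy_population()
        cfg = GeneratorConfig(n_cases=4, n_controls=4, population_size=10,
                              n_proteins=1, n_below_lod=0,
                              true_log_or=np.zeros(1), seed=0)
        cohort = risk_set_match(pop, cfg)
        ctrl_pids = set(cohort.loc[cohort["is_case"] == 0, "person_id"])
        case_pids = set(cohort.loc[cohort["is_case"] == 1, "person_id"])
        assert 3 in ctrl_pids and 3 in case_pids


class TestProteins:
    def test_engineered_below_lod_assays_fail_the_filter(self, small_study):
        _, cohort, matrix, meta, truth = small_study
        _, exclusions = filter_by_lod(matrix, meta)
        assert set(exclusions["assay"]) == set(
            truth.loc[truth["below_lod"] == 1, "assay"]
        )

    def test_null_config_gives_uncorrelated_expression(self):
        cfg = small_config(true_log_or=np.zeros(12), n_below_lod=0,
                           correlation_block_spec=((1, 0.0),), seed=11)
        cohort, matrix, _, _ = generate_study(cfg)
        rho = matrix.corr(method="spearman").to_numpy()
        off = rho[np.triu_indices(12, 1)]
        assert abs(off.mean()) < 0.05

    def test_block_correlation_is_planted(self):
        cfg = small_config(true_log_or=np.zeros(12), n_below_lod=0,
                           correlation_block_spec=((4, 0.5),), seed=11)
        _, matrix, _, _ = generate_study(cfg)
        within = matrix.iloc[:, :4].corr().to_numpy()[np.triu_indices(4, 1)]
        between = matrix.iloc[:, [0, 4, 8]].corr().to_numpy()[np.triu_indices(3, 1)]
        assert within.mean() == pytest.approx(0.5, abs=0.12)
        assert abs(between.mean()) < 0.12


class TestConfig:
    @pytest.mark.parametrize(
        "kw",
        [
            {"n_cases": 0},
            {"n_controls": 999},
            {"surgery_fraction": 0.0},
            {"n_below_lod": 99},
            {"correlation_block_spec": ((4, 1.0),)},
            {"lod_quantile": 1.5},
        ],
    )
    def test_invalid_config_rejected(self, kw):
        with pytest.raises(ConfigError):
            small_config(**kw)

    def test_yaml_round_trip(self, tmp_path):
        cfg = small_config()
        cfg.to_yaml(tmp_path / "cfg.yaml")
        back = GeneratorConfig.from_yaml(tmp_path / "cfg.yaml")
        assert back.n_cases == cfg.n_cases
        np.testing.assert_allclose(back.true_log_or, cfg.true_log_or)
        assert back.correlation_block_spec == cfg.correlation_block_spec


class TestDeterminism:
    def test_identical_seed_gives_byte_identical_tables(self, tmp_path):
        cfg = small_config()
        out = []
        for d in ("a", "b"):
            cohort, matrix, meta, truth = generate_study(cfg)
            paths = write_study(tmp_path / d, cohort, matrix, meta, truth, cfg)
            out.append(paths)
        for name in ("subjects", "matrix", "assay_meta", "truth"):
            with open(out[0][name], "rb") as f1, open(out[1][name], "rb") as f2:
                assert f1.read() == f2.read()

    def test_different_seeds_differ(self):
        a = generate_study(small_config(seed=1))[1]
        b = generate_study(small_config(seed=2))[1]
        assert a.shape != b.shape or not np.allclose(a.to_numpy(), b.to_numpy())
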