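import math

import numpy as np
import pytest

from twosample_mr.estimators import MREstimate
from twosample_mr.frailty import (
    Cohort,
    FrailtyConfig,
    FrailtyReplicate,
    FrailtyResult,
    GompertzMakehamParams,
    IncidenceTable,
    apply_mortality,
    assign_disease,
    one_sample_test,
    run_frailty,
    run_replicate,
    simulate_cohort,
)


def strong_config(**kw):
    """Small, well-powered configuration for fast null checks: five strong
    instruments, generous case sampling."""
    rng = np.random.default_rng(123)
    eaf = rng.uniform(0.2, 0.8, 5)
    beta = np.sqrt(0.1 / 5 / (2 * eaf * (1 - eaf)))
    defaults = dict(
        instruments=[(f"s{i}", float(p), float(b)) for i, (p, b) in
                     enumerate(zip(eaf, beta))],
        exposure_kind="continuous",
        exposure_mean=7.6,
        exposure_sd=8.0,
        hazard_ratio=1.0,
        n_pop=50_000,
        n_replicates=50,
        n_case_sample=500,
        n_control_sample=12_000,
        seed=0,
    )
    defaults.update(kw)
    return FrailtyConfig(**defaults)


class TestSimulateCohort:
    def test_genotype_mean_matches_binomial(self):
        cfg = strong_config(instruments=[("s0", 0.5, 0.1)], n_pop=100_000)
        cohort = simulate_cohort(cfg, np.random.default_rng(1))
        assert cohort.genotypes.mean() == pytest.approx(1.0, abs=0.01)

    def test_exposure_mean_sd_match_config(self):
        cfg = strong_config(n_pop=1_000_000)
        cohort = simulate_cohort(cfg, np.random.default_rng(2))
        assert cohort.exposure.mean() == pytest.approx(7.6, rel=0.01)
        assert cohort.exposure.std() == pytest.approx(8.0, rel=0.01)

    def test_null_betas_give_uncorrelated_exposure(self):
        cfg = strong_config(
            instruments=[("s0", 0.3, 0.0), ("s1", 0.5, 0.0)], n_pop=250_000
        )
        cohort = simulate_cohort(cfg, np.random.default_rng(3))
        for j in range(2):
            r = np.corrcoef(cohort.genotypes[:, j], cohort.exposure)[0, 1]
            assert abs(r) < 0.01

    def test_binary_exposure_prevalence(self):
        cfg = strong_config(exposure_kind="binary", exposure_mean=0.5,
                            n_pop=200_000)
        cohort = simulate_cohort(cfg, np.random.default_rng(4))
        assert cohort.exposure.mean() == pytest.approx(0.5, abs=0.01)
        assert set(np.unique(cohort.exposure)) <= {0.0, 1.0}


class TestMortality:
    def test_survival_probability_one_at_age_zero(self):
        gm = GompertzMakehamParams()
        assert math.exp(-gm.cumulative_hazard(np.array([0.0]))[0]) == pytest.approx(1.0)

    def test_null_hr_survival_independent_of_exposure(self):
        cfg = strong_config(hazard_ratio=1.0, n_pop=200_000)
        rng = np.random.default_rng(5)
        cohort = simulate_cohort(cfg, rng)
        alive = apply_mortality(cohort, cfg, rng)
        r_exposed = alive[cohort.exposed].mean()
        r_other = alive[~cohort.exposed].mean()
        # binomial 2-SE band on the difference
        se = math.sqrt(
            r_exposed * (1 - r_exposed) / cohort.exposed.sum()
            + r_other * (1 - r_other) / (~cohort.exposed).sum()
        )
        assert abs(r_exposed - r_other) < 2.5 * se + 1e-3

    def test_survival_decreases_with_hazard_ratio(self):
        rng = np.random.default_rng(6)
        cfg1 = strong_config(n_pop=100_000)
        cohort = simulate_cohort(cfg1, rng)
        survival = []
        for hr in (1.0, 1.5, 2.0, 3.0):
            cfg = strong_config(hazard_ratio=hr, n_pop=100_000)
            gm_h = cfg.gm_params.cumulative_hazard(cohort.age[cohort.exposed])
            survival.append(float(np.exp(-hr * gm_h).mean()))
        assert all(a > b for a, b in zip(survival, survival[1:]))


class TestDisease:
    def test_zero_incidence_gives_no_cases(self):
        cfg = strong_config(incidence=IncidenceTable(probs=(0.0, 0.0, 0.0)))
        rng = np.random.default_rng(7)
        cohort = simulate_cohort(cfg, rng)
        alive = apply_mortality(cohort, cfg, rng)
        assert assign_disease(cohort, alive, cfg, rng).sum() == 0

    def test_band_ratio_reflected_in_case_fractions(self):
        cfg = strong_config(
            incidence=IncidenceTable(start_age=40, band_width=25,
                                     probs=(0.001, 0.01)),
            n_pop=1_000_000,
        )
        rng = np.random.default_rng(8)
        cohort = simulate_cohort(cfg, rng)
        alive = np.ones(cfg.n_pop, dtype=bool)
        disease = assign_disease(cohort, alive, cfg, rng)
        young = cohort.age < 65
        ratio = disease[~young].mean() / disease[young].mean()
        assert ratio == pytest.approx(10.0, rel=0.25)

    def test_dead_individuals_ineligible(self):
        cfg = strong_config()
        rng = np.random.default_rng(9)
        cohort = simulate_cohort(cfg, rng)
        alive = np.zeros(cfg.n_pop, dtype=bool)
        assert assign_disease(cohort, alive, cfg, rng).sum() == 0


class TestRunFrailty:
    def test_null_hr_frailty_or_near_one(self):
        """With no exposure-mortality link the frailty-only IVW OR is a clean
        null: geometric mean within [0.98, 1.02] over the replicates."""
        res = run_frailty(
            strong_config(n_replicates=200, n_pop=100_000,
                          n_case_sample=900, n_control_sample=20_000)
        )
        gmean = res.summary()["ivw"]["gmean_or"]
        assert 0.98 < gmean < 1.02

    def test_bias_magnitude_increases_with_hazard_ratio(self):
        biases = []
        for hr in (1.0, 1.8, 3.0):
            res = run_frailty(strong_config(hazard_ratio=hr, n_replicates=60,
                                            seed=11))
            biases.append(abs(res.summary()["ivw"]["mean_log_or"]))
        assert biases[2] > biases[0]
        assert biases[2] > 0.005

    def test_replicates_reproducible_in_isolation(self):
        cfg = strong_config(n_replicates=3)
        res = run_frailty(cfg)
        rep = res.replicates[1]
        again = run_replicate(cfg, rep.seed_used)
        assert again.ivw.beta == rep.ivw.beta

    def test_infeasible_strict_sampling_marks_failures(self):
        cfg = strong_config(n_case_sample=10**6, require_full_sample=True,
                            n_replicates=2)
        res = run_frailty(cfg)
        assert all(r.failed for r in res.replicates)
        assert res.summary()["n_replicates_ok"] == 0

    def test_write_outputs(self, tmp_path):
        res = run_frailty(strong_config(n_replicates=3))
        res.write(tmp_path)
        assert (tmp_path / "frailty_replicates.tsv").exists()
        assert (tmp_path / "frailty_summary.json").exists()


def _fake_result(log_ors):
    def est(b):
        return MREstimate("ivw", b, 0.1, b - 0.2, b + 0.2, 0.5, 5)

    reps = [FrailtyReplicate(est(b), None, est(b), 10, 100, i)
            for i, b in enumerate(log_ors)]
    cfg = strong_config(n_replicates=len(log_ors))
    return FrailtyResult(replicates=reps, config=cfg)


class TestOneSampleTest:
    def test_reference_at_mean_gives_p_one(self):
        res = _fake_result([0.1, 0.3])
        assert one_sample_test(res, 0.2) == pytest.approx(1.0)

    def test_far_reference_gives_tiny_p(self):
        rng = np.random.default_rng(12)
        draws = rng.normal(0.0, 0.05, 100)
        res = _fake_result(list(draws))
        assert one_sample_test(res, 0.5) < 1e-10

    def test_degenerate_distribution_exact_comparison(self):
        res = _fake_result([0.2, 0.2, 0.2])
        assert one_sample_test(res, 0.2) == 1.0
        assert one_sample_test(res, 0.3) == 0.0


def test_config_from_yaml_file(tmp_path):
    import yaml

    payload = {
        "instruments": [["rs1", 0.3, 0.1], ["rs2", 0.5, 0.08]],
        "exposure_kind": "binary",
        "exposure_mean": 0.5,
        "hazard_ratio": 1.62,
        "gm_params": {"c": 4e-4, "a": 2e-5, "b": 0.1},
        "incidence": {"start_age": 40, "band_width": 10,
                      "probs": [0.001, 0.01, 0.02]},
        "n_pop": 1000,
        "n_replicates": 2,
        "n_case_sample": 5,
        "n_control_sample": 50,
        "seed": 3,
    }
    path = tmp_path / "frailty.yaml"
    path.write_text(yaml.safe_dump(payload))
    cfg = FrailtyConfig.from_file(path)
    assert cfg.instruments == [("rs1", 0.3, 0.1), ("rs2", 0.5, 0.08)]
    assert cfg.gm_params.b == 0.1
    assert cfg.incidence.probs == (0.001, 0.01, 0.02)
    path.write_text(yaml.safe_dump({**payload, "bogus": 1}))
    with pytest.raises(ValueError, match="unknown frailty config keys"):
        FrailtyConfig.from_file(path)
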