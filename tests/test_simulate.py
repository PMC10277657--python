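"""Cohort generator, case/control schemes, GWAS scans and release logic."""
import dataclasses

import numpy as np
import pytest
from scipy import stats as sps

from mrbias.simulate import (SCHEMES, Cohort, ReleaseSpec, ScenarioConfig,
                             apply_scheme, gwas, load_scenario,
                             scheme_estimand, simulate_cohort,
                             simulate_ldsc_sumstats, simulate_panel,
                             simulate_releases, simulate_study)


def _toy_cohort():
    """Six individuals with hand-set flags (last one severe)."""
    flags = dict(
        infected=np.array([1, 1, 1, 0, 0, 1], bool),
        tested=np.array([1, 1, 0, 1, 0, 1], bool),
        hospitalised=np.array([1, 0, 0, 0, 0, 1], bool),
        severe=np.array([0, 0, 0, 0, 0, 1], bool),
    )
    n = 6
    panel = simulate_panel(ScenarioConfig(n=n, m=5, n_exposure_variants=2,
                                          n_sep_variants=1,
                                          n_disease_variants=1),
                           np.random.default_rng(0))
    return Cohort(panel=panel, genotypes=np.zeros((n, 5), np.int8),
                  sep=np.zeros(n), exposure=np.zeros(n),
                  severity_score=(flags["infected"].astype(np.int8)
                                  + flags["hospitalised"]
                                  + flags["severe"]),
                  d1_positive=np.zeros(n, bool), era=np.zeros(n, int), **flags)


class TestSchemes:
    def test_a1_labels_by_hand(self):
        # cases: severe tested hospitalised; controls: confirmed not admitted
        # by hand: case = severe & confirmed -> individual 5 only; control =
        # confirmed & not admitted -> individual 1 only (individual 0 is
        # admitted but not severe -> excluded; individual 2 is untested)
        labels, counts = apply_scheme(_toy_cohort(), "A1")
        assert counts == {"cases": 1, "controls": 1, "excluded": 4}
        assert labels[5] == 1 and labels[1] == 0 and labels[0] == -1

    def test_c2_population_controls_contain_untested_infected(self):
        labels, counts = apply_scheme(_toy_cohort(), "C2")
        assert counts == {"cases": 3, "controls": 3, "excluded": 0}
        # individual 2 is infected but untested -> misclassified as control
        assert labels[2] == 0

    def test_b1_with_nobody_tested_not_estimable(self):
        cohort = _toy_cohort()
        cohort.tested[:] = False
        _, counts = apply_scheme(cohort, "B1")
        assert counts["cases"] == 0 and counts["controls"] == 0

    def test_case_control_disjoint_for_all_schemes(self):
        cohort = _toy_cohort()
        for name, scheme in SCHEMES.items():
            cases = scheme.case(cohort)
            controls = scheme.control(cohort) & ~cases
            assert not np.any(cases & controls), name


class TestSimulateCohort:
    def test_severity_ordering_invariant(self, small_cfg):
        cohort = simulate_cohort(small_cfg, np.random.default_rng(0))
        assert np.all(cohort.infected[cohort.hospitalised])
        assert np.all(cohort.hospitalised[cohort.severe])

    def test_determinism(self, small_cfg):
        c1 = simulate_cohort(small_cfg, np.random.default_rng(9))
        c2 = simulate_cohort(small_cfg, np.random.default_rng(9))
        np.testing.assert_array_equal(c1.genotypes, c2.genotypes)
        np.testing.assert_array_equal(c1.tested, c2.tested)
        np.testing.assert_allclose(c1.exposure, c2.exposure)

    def test_degenerate_prevalence_names_coefficient(self, small_cfg):
        bad = dataclasses.replace(small_cfg, a0=-60.0)
        with pytest.raises(Exception, match="a0"):
            simulate_cohort(bad, np.random.default_rng(0))

    def test_global_null_gwas_z_scores(self):
        # gamma = 0, theta = 0, no selection: exposure-GWAS z centred with
        # mean |z| near sqrt(2/pi)
        cfg = ScenarioConfig(n=6000, m=80, n_exposure_variants=0,
                             n_sep_variants=0, n_disease_variants=0,
                             theta=0.0)
        cohort = simulate_cohort(cfg, np.random.default_rng(4))
        stats = gwas(cohort, "exposure")
        z = stats.data["beta"] / stats.data["se"]
        assert abs(np.mean(np.abs(z)) - np.sqrt(2 / np.pi)) < 0.15
        # case status independent of genotype: p values not enriched
        labels, _ = apply_scheme(cohort, "C2")
        cstats = gwas(cohort, labels)
        assert (cstats.data["pvalue"] < 5e-8).sum() == 0

    def test_logistic_recovery_of_infection_effect(self):
        # a direct logistic fit of infection on exposure recovers the
        # marginal estimand (Monte-Carlo oracle at n=20000)
        cfg = ScenarioConfig(n=20_000, m=20, n_exposure_variants=10,
                             n_sep_variants=0, n_disease_variants=0)
        cohort = simulate_cohort(cfg, np.random.default_rng(12))
        from mrbias.simulate import _logistic_scan
        b, se, ok = _logistic_scan(cohort.exposure[:, None],
                                   cohort.infected.astype(np.int8))
        assert ok[0]
        # conditional theta=0.3 attenuates toward the marginal slope
        assert abs(b[0] - 0.3) < 0.1


class TestGwasScans:
    def test_phenotype_equal_to_dosage(self, small_cfg):
        cohort = simulate_cohort(small_cfg, np.random.default_rng(2))
        y = cohort.genotypes[:, 0].astype(float)
        stats = gwas(cohort, y, trait_name="dosage")
        row = stats.data.set_index("variant_id").loc["rs1"]
        assert row["beta"] == pytest.approx(1.0, abs=1e-10)
        assert row["pvalue"] < 1e-100

    def test_logistic_scan_matches_statsmodels(self, small_cfg):
        # independent oracle: statsmodels ML logistic per variant
        import statsmodels.api as sm
        cohort = simulate_cohort(small_cfg, np.random.default_rng(3))
        labels, _ = apply_scheme(cohort, "C2")
        stats = gwas(cohort, labels)
        sub = stats.data.head(4)
        for _, row in sub.iterrows():
            j = int(row["variant_id"][2:]) - 1
            X = sm.add_constant(cohort.genotypes[:, j].astype(float))
            fit = sm.Logit((labels == 1).astype(int), X).fit(disp=0)
            assert row["beta"] == pytest.approx(fit.params[1], abs=1e-5)
            assert row["se"] == pytest.approx(fit.bse[1], rel=1e-3)

    def test_permuted_labels_give_uniform_pvalues(self):
        cfg = ScenarioConfig(n=2000, m=500, n_exposure_variants=100,
                             n_sep_variants=50, n_disease_variants=50)
        cohort = simulate_cohort(cfg, np.random.default_rng(8))
        labels, _ = apply_scheme(cohort, "C2")
        rng = np.random.default_rng(1)
        permuted = rng.permutation(labels)
        stats = gwas(cohort, permuted)
        ks = sps.kstest(stats.data["pvalue"], "uniform")
        assert ks.pvalue > 0.01

    def test_monomorphic_variant_dropped(self, small_cfg):
        cohort = simulate_cohort(small_cfg, np.random.default_rng(5))
        cohort.genotypes[:, 3] = 0
        labels, _ = apply_scheme(cohort, "C2")
        stats = gwas(cohort, labels)
        assert "rs4" not in set(stats.data["variant_id"])


class TestReleases:
    def test_tested_fraction_monotone_in_policy(self, small_cfg):
        cfg = dataclasses.replace(small_cfg, releases=[
            ReleaseSpec("r3", 0.25, -2.0), ReleaseSpec("r4", 0.5, 0.0),
            ReleaseSpec("r5", 0.75, 1.5), ReleaseSpec("r6", 1.0, 3.0)])
        cohort = simulate_cohort(cfg, np.random.default_rng(6))
        fracs = [cohort.tested[cohort.era == k].mean() for k in range(4)]
        assert fracs == sorted(fracs)

    def test_single_release_equals_single_cohort_pipeline(self, small_cfg):
        cohort = simulate_cohort(small_cfg, np.random.default_rng(7))
        outcomes, counts = simulate_releases(small_cfg, cohort, ["C2"])
        labels, direct_counts = apply_scheme(cohort, "C2")
        assert counts["r6"]["C2"] == direct_counts
        direct = gwas(cohort, labels, trait_name="covid_C2",
                      release_tag="r6")
        np.testing.assert_allclose(outcomes["r6"]["C2"].data["beta"],
                                   direct.data["beta"])

    def test_study_is_two_sample_and_truth_serialises(self, small_cfg):
        study = simulate_study(small_cfg, seed=3, schemes=["C1", "C2"])
        assert study.exposure_stats.trait_type == "quantitative"
        assert study.outcomes["r6"]["C2"].trait_type == "binary"
        payload = study.truth.to_json()
        assert '"theta": 0.3' in payload


class TestScenarioConfigs:
    def test_packaged_scenarios_load(self):
        for name in ("S0", "S1", "S2", "S3", "S4"):
            cfg = load_scenario(name)
            assert cfg.n == 20_000 and cfg.m == 100
        s5 = load_scenario("S5")
        assert s5.rg == 0.3 and s5.M == 5000

    def test_yaml_roundtrip(self, tmp_path, small_cfg):
        small_cfg.to_yaml(tmp_path / "cfg.yaml")
        back = ScenarioConfig.from_yaml(tmp_path / "cfg.yaml")
        assert back == small_cfg

    def test_release_fraction_validation(self):
        with pytest.raises(ValueError):
            ScenarioConfig(releases=[ReleaseSpec("a", 0.5, 0.0),
                                     ReleaseSpec("b", 0.4, 0.0)])


class TestEstimandOracle:
    def test_no_selection_estimand_below_conditional_theta(self):
        cfg = load_scenario("S0")
        val = scheme_estimand(cfg, "infection", n=200_000, seed=0)
        assert 0 < val < cfg.theta  # non-collapsibility attenuates

    def test_c1_conditioning_bias_direction(self):
        # under S1 selection, conditioning on being tested (C1) distorts the
        # estimand away from the unselected infection estimand
        cfg = load_scenario("S1")
        base = scheme_estimand(cfg, "infection", n=300_000, seed=1)
        c1 = scheme_estimand(cfg, "C1", n=300_000, seed=1)
        assert abs(c1 - base) > 0.01

    def test_population_controls_attenuate_estimand(self):
        cfg = dataclasses.replace(load_scenario("S2"), releases=[
            ReleaseSpec("r6", 1.0, -0.5)])
        c1 = scheme_estimand(cfg, "C1", n=300_000, seed=2)
        c2 = scheme_estimand(cfg, "C2", n=300_000, seed=2)
        assert abs(c2) < abs(c1)


class TestLdscGenerator:
    def test_rg_one_noiseless_limit(self):
        s1, s2, ld = simulate_ldsc_sumstats(0.5, 0.5, 1.0, 2000,
                                            5_000_000, 5_000_000, seed=1)
        z1 = s1.data["beta"] / s1.data["se"]
        z2 = s2.data["beta"] / s2.data["se"]
        assert np.corrcoef(z1, z2)[0, 1] > 0.99

    def test_rejects_bad_rg(self):
        with pytest.raises(ValueError):
            simulate_ldsc_sumstats(0.5, 0.5, 1.5, 100, 1000, 1000, seed=0)
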