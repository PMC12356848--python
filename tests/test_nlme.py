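"""Population NLME fit: transforms, recovery, ages, and optimality."""

import math

import numpy as np
import pandas as pd
import pytest

from hgsoc_kinetics import (
    Cohort,
    GompertzParams,
    LesionSeries,
    Site,
    TumorGrowthNLME,
    build_transformed,
    gompertz_y,
    volume_at,
)
from hgsoc_kinetics.gompertz import DAYS_PER_MONTH
from hgsoc_kinetics.nlme import SubjectSeries, TransformedDataset, auto_vinf


def _noiseless_series(pid, beta, t1, vinf, dt_months, site="ovary_pelvis"):
    p = GompertzParams(vinf=vinf, beta=beta)
    days = tuple(dt * DAYS_PER_MONTH for dt in dt_months)
    vols = tuple(volume_at(p, t1 + dt) for dt in dt_months)
    return LesionSeries(patient_id=pid, site=Site.parse(site), scan_days=days, volumes=vols)


def _model_dataset(n, theta_pop, D, lam, dts, seed, law="gompertz"):
    """Data generated directly from the transformed-scale NLME equations."""
    rng = np.random.default_rng(seed)
    theta_pop = np.asarray(theta_pop, dtype=float)
    dts = np.asarray(dts, dtype=float)
    subs = []
    for i in range(n):
        th = theta_pop + rng.multivariate_normal([0.0, 0.0], D)
        y = np.exp(th[0]) + np.exp(th[1]) * dts + lam * rng.normal(size=len(dts))
        subs.append(SubjectSeries(f"s{i:03d}", dts, y))
    vinf = 800.0 if law == "gompertz" else None
    return TransformedDataset(tuple(subs), law, None, 1e-9, vinf)


class TestBuildTransformed:
    def test_noiseless_identity(self):
        # y = beta * (t1 + dt) exactly on a clean Gompertz trajectory
        beta, t1, vinf = 0.1, 20.0, 800.0
        series = [_noiseless_series(f"p{i}", beta, t1, vinf, [0.0, 1.0, 2.0]) for i in range(3)]
        cohort = Cohort(series=tuple(series))
        ds = build_transformed(cohort, "ovary_pelvis", vinf=vinf)
        for s in ds.subjects:
            np.testing.assert_allclose(s.y, beta * (t1 + s.dt), rtol=1e-10)
            assert s.dt[0] == 0.0

    def test_volume_at_vinf_rejected(self):
        s = LesionSeries("A", Site.OVARY_PELVIS, (0.0, 30.0), (1.0, 800.0))
        cohort = Cohort(series=(s,))
        with pytest.raises(ValueError, match="A.*Vinf"):
            build_transformed(cohort, "ovary_pelvis", vinf=800.0)

    def test_matches_elementwise_formula(self, default_cohort):
        cohort, _ = default_cohort
        vinf = auto_vinf(cohort, "omentum")
        ds = build_transformed(cohort, "omentum", vinf=vinf)
        k = math.log(vinf / 1e-9)
        by_id = {s.patient_id: s for s in cohort.by_site("omentum")}
        for sub in ds.subjects:
            raw = by_id[sub.subject_id]
            expected = [-math.log(1.0 - math.log(v / 1e-9) / k) for v in raw.volumes]
            np.testing.assert_allclose(sub.y, expected, rtol=1e-12)

    def test_auto_vinf_exceeds_max_volume(self, default_cohort):
        cohort, _ = default_cohort
        vmax = max(v for s in cohort.by_site("omentum") for v in s.volumes)
        assert auto_vinf(cohort, "omentum") > vmax


class TestFit:
    def test_degenerate_no_heterogeneity_recovers_exactly(self):
        # identical noiseless subjects: the fit must reduce to nonlinear
        # least squares and return the generating parameters
        beta, t1 = 0.1, 20.0
        dts = np.array([0.0, 1.0, 2.5])
        y = beta * (t1 + dts)
        subs = tuple(SubjectSeries(f"s{i}", dts, y.copy()) for i in range(5))
        res = TumorGrowthNLME(TransformedDataset(subs, "gompertz", None, 1e-9, 800.0)).fit()
        expected = np.array([math.log(beta * t1), math.log(beta)])
        np.testing.assert_allclose(res.params, expected, atol=1e-6)
        assert res.population_age().t1_pop == pytest.approx(t1, abs=1e-5)

    def test_parameter_recovery_within_three_se(self):
        theta = np.array([math.log(0.1 * 20.0), math.log(0.1)])
        D = np.diag([0.04, 0.09])
        ds = _model_dataset(50, theta, D, lam=0.05, dts=[0.0, 1.0, 2.0, 3.0], seed=21)
        res = TumorGrowthNLME(ds).fit()
        for est, true, se in zip(res.params, theta, res.bse):
            assert abs(est - true) < 3.0 * se

    def test_tiny_instance_local_optimality(self):
        # the linearised log-likelihood at the optimum beats random
        # perturbations of (theta, D, lambda)
        ds = _model_dataset(3, [0.7, -2.3], np.diag([0.02, 0.05]), 0.05, [0.0, 1.5], seed=4)
        res = TumorGrowthNLME(ds).fit()
        best = res.linearized_neg2ll()
        rng = np.random.default_rng(9)
        for _ in range(100):
            dth = rng.normal(0, 0.05, 2)
            dlog = rng.normal(0, 0.1, 2)
            Dp = res.D + np.diag(np.exp(dlog) * np.diag(res.D)) - np.diag(np.diag(res.D))
            lamp = res.lam * math.exp(rng.normal(0, 0.1))
            val = res.linearized_neg2ll(res.params + dth, Dp, lamp)
            assert val >= best - 1e-6

    def test_estimates_invariant_under_subject_relabelling(self):
        ds = _model_dataset(20, [0.7, -2.3], np.diag([0.04, 0.09]), 0.05, [0.0, 1.0], seed=13)
        res_a = TumorGrowthNLME(ds).fit()
        perm = TransformedDataset(ds.subjects[::-1], ds.law, ds.site, ds.v0, ds.vinf)
        res_b = TumorGrowthNLME(perm).fit()
        np.testing.assert_allclose(res_a.params, res_b.params, rtol=1e-5, atol=1e-7)

    def test_fewer_than_three_subjects_rejected(self):
        ds = _model_dataset(2, [0.7, -2.3], np.diag([0.01, 0.01]), 0.01, [0.0, 1.0], seed=1)
        with pytest.raises(ValueError, match="3 subjects"):
            TumorGrowthNLME(ds)

    def test_first_observation_must_anchor_time(self):
        with pytest.raises(ValueError, match="dt = 0"):
            TransformedDataset(
                (SubjectSeries("s0", np.array([1.0, 2.0]), np.array([1.0, 2.0])),),
                "gompertz",
                None,
                1e-9,
                800.0,
            )


class TestPopulationAge:
    def test_point_estimate_algebra(self):
        ds = _model_dataset(5, [math.log(0.1 * 20.0), math.log(0.1)], np.diag([1e-4, 1e-4]), 1e-4, [0.0, 1.0], seed=2)
        res = TumorGrowthNLME(ds).fit()
        res.params = np.array([math.log(0.1 * 20.0), math.log(0.1)])
        res.cov_params_matrix = np.zeros((2, 2))
        age = res.population_age()
        assert age.t1_pop == pytest.approx(20.0, rel=1e-12)
        # zero standard errors collapse the CI onto the point
        assert age.ci95 == (pytest.approx(20.0), pytest.approx(20.0))

    def test_ci_contains_point_and_shrinks_with_n(self):
        theta = [0.7, -2.3]
        D = np.diag([0.04, 0.09])
        widths = []
        for n, seed in [(10, 31), (100, 32)]:
            res = TumorGrowthNLME(_model_dataset(n, theta, D, 0.05, [0.0, 1.0, 2.0], seed=seed)).fit()
            age = res.population_age()
            assert age.ci95[0] <= age.t1_pop <= age.ci95[1]
            widths.append(age.ci95[1] - age.ci95[0])
        assert widths[1] < widths[0]


class TestIndividualAges:
    def test_algebra_from_empirical_bayes_modes(self):
        ds = _model_dataset(5, [0.7, -2.3], np.diag([0.04, 0.09]), 0.05, [0.0, 1.0], seed=6)
        res = TumorGrowthNLME(ds).fit()
        theta_i = res.params[None, :] + res.random_effects
        expected = np.exp(theta_i[:, 0] - theta_i[:, 1])
        np.testing.assert_allclose(res.individual_ages().to_numpy(), expected, rtol=1e-12)

    def test_shrinkage_limit_all_ages_equal_population(self):
        beta, t1 = 0.1, 20.0
        dts = np.array([0.0, 1.0])
        y = beta * (t1 + dts)
        subs = tuple(SubjectSeries(f"s{i}", dts, y.copy()) for i in range(4))
        res = TumorGrowthNLME(TransformedDataset(subs, "gompertz", None, 1e-9, 800.0)).fit()
        ages = res.individual_ages()
        np.testing.assert_allclose(ages, res.population_age().t1_pop, rtol=1e-5)

    def test_rank_correlation_with_true_ages(self):
        from scipy.stats import spearmanr

        rng = np.random.default_rng(17)
        theta = np.array([math.log(0.1 * 20.0), math.log(0.1)])
        D = np.diag([0.04, 0.09])
        dts = np.array([0.0, 1.0, 2.0, 4.0])
        subs, true_t1 = [], []
        for i in range(60):
            th = theta + rng.multivariate_normal([0, 0], D)
            true_t1.append(math.exp(th[0] - th[1]))
            y = np.exp(th[0]) + np.exp(th[1]) * dts + 0.05 * rng.normal(size=len(dts))
            subs.append(SubjectSeries(f"s{i:03d}", dts, y))
        res = TumorGrowthNLME(TransformedDataset(tuple(subs), "gompertz", None, 1e-9, 800.0)).fit()
        rho = spearmanr(true_t1, res.individual_ages().to_numpy()).statistic
        assert rho > 0.8


class TestLawComparison:
    def test_exponential_age_exceeds_gompertz_on_decelerating_growth(self, big_cohort):
        # with decelerating (Gompertz) data, a constant-rate model must
        # back-project older lesions: small tumours are assumed to have
        # grown as slowly as observed at scan time
        cohort, _ = big_cohort
        for site in ("ovary_pelvis", "omentum"):
            t1_g = TumorGrowthNLME.from_cohort(cohort, site, law="gompertz").fit().population_age().t1_pop
            t1_e = TumorGrowthNLME.from_cohort(cohort, site, law="exponential").fit().population_age().t1_pop
            assert t1_e > t1_g

    def test_summary_mentions_key_quantities(self, default_cohort):
        cohort, _ = default_cohort
        res = TumorGrowthNLME.from_cohort(cohort, "ovary_pelvis").fit()
        text = res.summary()
        assert "gompertz" in text and "t1_pop" in text and "std err" in text
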