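"""Penalized-likelihood LMS fitting: oracles, recovery, edge cases."""

import warnings

import numpy as np
import pytest

import gripref as g
from gripref import published as pub
from gripref.fit import FitConfig, LMSCurveModel, fit_lms, predict_lms, select_edf


def make_records(ages, values, sex="boys"):
    recs = []
    for i, (a, y) in enumerate(zip(ages, values)):
        recs.append(g.CohortRecord(
            id=f"t{i}", sex=sex, age=int(a), height=160.0, weight=45.0,
            bmi=45.0 / 1.6**2, hgs_left=y, hgs_right=y, hgs_abs=y,
        ))
    return recs


def simulate_one_sex(sex, seed, n=300):
    rng = np.random.default_rng(seed)
    recs = []
    for age in pub.AGES:
        vals = g.bccg_sample(pub.LMS_TRIPLES[sex][age], n, rng)
        recs.extend(make_records([age] * n, vals, sex=sex))
    return recs


class TestGaussianOracle:
    def test_lambda_frozen_at_one_reproduces_gaussian_mle(self):
        """At lam = 1 with constant curves the fit is the Gaussian MLE."""
        rng = np.random.default_rng(42)
        y = rng.normal(30.0, 5.0, 400)
        y = y[y > 0]
        recs = make_records([14] * len(y), y)
        cfg = FitConfig(edf_lambda=1, edf_mu=1, edf_sigma=1, fix_lambda=1.0)
        model = fit_lms(recs, cfg)
        t = predict_lms(model, 14)
        mean, sd = float(np.mean(y)), float(np.std(y))  # MLE (ddof=0)
        assert t.mu == pytest.approx(mean, rel=1e-4)
        assert t.sigma == pytest.approx(sd / mean, rel=1e-4)

    def test_lambda_estimated_on_gaussian_data_near_one(self):
        rng = np.random.default_rng(5)
        recs = []
        for age in pub.AGES:
            y = np.abs(rng.normal(30.0, 4.5, 300))
            recs.extend(make_records([age] * 300, y))
        cfg = FitConfig(edf_lambda=1, edf_mu=3, edf_sigma=1)
        model = fit_lms(recs, cfg)
        lam_hat = predict_lms(model, 14).lam
        assert abs(lam_hat - 1.0) < 0.3


class TestDegenerateInputs:
    def test_zero_variance_cohort_pins_mu_and_floors_sigma(self):
        recs = make_records([13] * 60 + [14] * 60, [20.0] * 120)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = fit_lms(recs)
        t = predict_lms(model, 13)
        assert t.mu == pytest.approx(20.0, rel=1e-6)
        assert t.sigma < 1e-3  # driven to the lower bound

    def test_single_age_cohort_fits_constant_triples(self):
        rng = np.random.default_rng(0)
        vals = g.bccg_sample(pub.LMS_TRIPLES["boys"][14], 200, rng)
        model = fit_lms(make_records([14] * 200, vals))
        assert len(model.knot_ages) == 1
        t = model.predict(14)
        assert t.mu == pytest.approx(pub.LMS_TRIPLES["boys"][14].mu, rel=0.1)

    def test_mixed_sex_cohort_rejected(self):
        recs = make_records([13] * 40, [20.0] * 40, sex="boys") + \
            make_records([13] * 40, [15.0] * 40, sex="girls")
        with pytest.raises(ValueError, match="single-sex"):
            fit_lms(recs)

    def test_nonpositive_strength_rejected(self):
        recs = make_records([13] * 40, [20.0] * 39 + [0.0])
        with pytest.raises(ValueError, match="> 0"):
            fit_lms(recs)

    def test_thin_stratum_warns(self):
        rng = np.random.default_rng(0)
        recs = make_records([13] * 5, g.bccg_sample(pub.LMS_TRIPLES["boys"][13], 5, rng))
        recs += make_records([14] * 60, g.bccg_sample(pub.LMS_TRIPLES["boys"][14], 60, rng))
        with pytest.warns(UserWarning, match="fewer than"):
            fit_lms(recs)


class TestConvergence:
    def test_penalized_deviance_non_increasing(self, boys_model):
        path = boys_model.fit_stats["deviance_path"]
        tol = 1e-6
        assert all(path[i + 1] <= path[i] + tol for i in range(len(path) - 1))

    def test_converged_flag_and_valid_predictions(self, boys_model):
        assert boys_model.fit_stats["converged"]
        for age in np.linspace(12, 16, 17):
            t = predict_lms(boys_model, float(age))
            assert t.mu > 0 and t.sigma > 0

    def test_extrapolation_warns_not_errors(self, boys_model):
        with pytest.warns(UserWarning, match="extrapolating"):
            t = predict_lms(boys_model, 17.5)
        assert t.mu > 0


class TestRecovery:
    def test_median_curve_recovery_across_seeds(self):
        """Median recovery errors over seeds: mu < 2%, sigma < 10%, lam < 0.3."""
        n_seeds = 20
        mu_err = {a: [] for a in pub.AGES}
        sig_err = {a: [] for a in pub.AGES}
        lam_err = {a: [] for a in pub.AGES}
        for seed in range(n_seeds):
            recs = simulate_one_sex("boys", seed)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = fit_lms(recs)
            for a in pub.AGES:
                t = predict_lms(model, a)
                true = pub.LMS_TRIPLES["boys"][a]
                mu_err[a].append(abs(t.mu - true.mu) / true.mu)
                sig_err[a].append(abs(t.sigma - true.sigma) / true.sigma)
                lam_err[a].append(abs(t.lam - true.lam))
        for a in pub.AGES:
            assert np.median(mu_err[a]) < 0.02
            assert np.median(sig_err[a]) < 0.10
            assert np.median(lam_err[a]) < 0.3

    def test_fitted_median_tracks_generating_medians(self, boys_model):
        for a in pub.AGES:
            true_mu = pub.LMS_TRIPLES["boys"][a].mu
            assert predict_lms(boys_model, a).mu == pytest.approx(true_mu, rel=0.03)

    def test_median_curve_monotone_over_age(self, boys_model):
        grid = np.linspace(12, 16, 41)
        mus = [predict_lms(boys_model, float(a)).mu for a in grid]
        assert np.all(np.diff(mus) > 0)

    def test_sex_separation_at_age_16(self):
        ratios = []
        for seed in range(5):
            cohort = g.generate_cohort(g.default_spec(seed=seed))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                bm = fit_lms([r for r in cohort if r.sex == "boys"])
                gm = fit_lms([r for r in cohort if r.sex == "girls"])
            ratios.append(predict_lms(bm, 16).mu / predict_lms(gm, 16).mu)
        expected = pub.LMS_TRIPLES["boys"][16].mu / pub.LMS_TRIPLES["girls"][16].mu
        assert np.median(ratios) == pytest.approx(expected, rel=0.05)

    def test_constant_parameter_simulation_recovers_constant(self):
        rng = np.random.default_rng(11)
        lms = g.LMSTriple(lam=0.5, mu=25.0, sigma=0.3)
        recs = []
        for age in pub.AGES:
            recs.extend(make_records([age] * 300, g.bccg_sample(lms, 300, rng)))
        model = fit_lms(recs)
        triples = [predict_lms(model, a) for a in pub.AGES]
        mus = [t.mu for t in triples]
        assert np.ptp(mus) / np.mean(mus) < 0.05
        for t in triples:
            assert t.mu == pytest.approx(25.0, rel=0.03)


class TestSelectEdf:
    def test_single_candidate_returned(self, boys):
        cfg = FitConfig(edf_mu=2)
        assert select_edf(boys[:600], [cfg]) is cfg

    def test_identical_candidates_tie_break_by_order(self, boys):
        a, b = FitConfig(edf_mu=2), FitConfig(edf_mu=2)
        assert select_edf(boys[:600], [a, b]) is a

    def test_linear_median_prefers_low_edf(self):
        # boys' generating M(t) is nearly linear in age
        recs = simulate_one_sex("boys", 3)
        grid = [FitConfig(edf_mu=edf) for edf in (2, 3, 4, 5)]
        chosen = select_edf(recs, grid)
        assert chosen.edf_mu <= 3

    def test_empty_grid_rejected(self, boys):
        with pytest.raises(ValueError, match="empty"):
            select_edf(boys, [])


class TestSerialization:
    def test_text_round_trip_exact(self, boys_model):
        restored = LMSCurveModel.from_text(boys_model.to_text())
        assert restored.sex == boys_model.sex
        assert np.allclose(restored.knot_ages, boys_model.knot_ages, atol=1e-12)
        for p in ("lam", "mu", "sigma"):
            assert np.allclose(restored.coef[p], boys_model.coef[p], atol=1e-12)
            assert restored.link[p] == boys_model.link[p]
        for age in (12.0, 13.7, 16.0):
            a, b = predict_lms(restored, age), predict_lms(boys_model, age)
            assert a.mu == pytest.approx(b.mu, abs=1e-12)

    def test_unknown_format_rejected(self):
        with pytest.raises(ValueError, match="format"):
            LMSCurveModel.from_text("format: something-else\n")
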