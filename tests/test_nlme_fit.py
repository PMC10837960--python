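"""Marginal-likelihood estimation: identifiability, quadrature cross-check,
covariate model building, empirical-Bayes shrinkage and the bootstrap."""

import dataclasses as dc

import numpy as np
import pytest
from scipy import optimize

from alsmbma.trial_data import (Corpus, CovariateProfile, ScorePoint,
                                StudyArm, SurvivalPoint)
from alsmbma.alsfrs_model import (EmaxParams, typical_change,
                                  REFERENCE_ARM_SIZE)
from alsmbma.os_model import to_obs_scale
from alsmbma.reference import PLACEBO_EMAX_PARAMS, PLACEBO_OS_PARAMS
from alsmbma.synthetic_data import GeneratorConfig, generate
from alsmbma.nlme_fit import (CovariateEffect, bootstrap, covariate_search,
                              empirical_bayes, evaluate_ofv, fit,
                              os_final_covariates, select_base_hazard)


@pytest.fixture(scope="module")
def noiseless_alsfrs_fit(noiseless_corpus):
    return fit(noiseless_corpus, "ALSFRS", n_starts=1, compute_se=False)


class TestNoiselessIdentifiability:
    def test_generating_values_minimize_ofv(self, noiseless_corpus):
        # at fixed (floored) variance components the generating structural
        # values beat any perturbed candidate
        base = dict(emax=26.2, et50=17.5, gamma=1.2, eta_sd_emax=1e-3,
                    eta_sd_gamma=1e-3, eps_sd=1e-3)
        ofv0 = evaluate_ofv(noiseless_corpus, "ALSFRS", base)
        for key in ("emax", "et50", "gamma"):
            for factor in (0.97, 1.03):
                alt = dict(base)
                alt[key] = base[key] * factor
                assert evaluate_ofv(noiseless_corpus, "ALSFRS", alt) > ofv0

    def test_fit_recovers_structural_parameters(self, noiseless_alsfrs_fit):
        e = noiseless_alsfrs_fit.estimates
        assert e["emax"] == pytest.approx(26.2, rel=0.01)
        assert e["et50"] == pytest.approx(17.5, rel=0.01)
        assert e["gamma"] == pytest.approx(1.2, rel=0.01)

    def test_eb_effects_near_zero(self, noiseless_alsfrs_fit):
        for eb in noiseless_alsfrs_fit.eb_effects.values():
            assert np.max(np.abs(eb["eta"])) < 0.02

    def test_os_thetas_recovered_exactly(self, noiseless_corpus):
        r = fit(noiseless_corpus, "OS", covariate_spec=os_final_covariates(),
                n_starts=1, compute_se=False)
        assert r.estimates["theta_duration"] == pytest.approx(0.0317,
                                                              abs=5e-4)
        assert r.estimates["theta_riluzole"] == pytest.approx(-0.228,
                                                              abs=5e-3)
        # mu/sigm sit on a flat ridge with the floored variance components
        # (study effects can absorb small location shifts), hence the
        # looser tolerance than for the covariate coefficients
        assert r.estimates["mu"] == pytest.approx(3.04, rel=0.05)
        assert r.estimates["sigm"] == pytest.approx(0.916, rel=0.05)


class TestRecoveryWithNoise:
    def test_alsfrs_single_seed(self):
        c = generate(GeneratorConfig(seed=3))
        r = fit(c, "ALSFRS", n_starts=2, compute_se=False)
        assert r.converged
        assert r.estimates["emax"] == pytest.approx(26.2, rel=0.25)
        assert r.estimates["et50"] == pytest.approx(17.5, rel=0.25)

    def test_os_single_seed(self):
        c = generate(GeneratorConfig(seed=104))
        r = fit(c, "OS", covariate_spec=os_final_covariates(), n_starts=2,
                compute_se=False)
        assert r.converged
        assert r.estimates["mu"] == pytest.approx(3.04, rel=0.10)
        assert r.estimates["sigm"] == pytest.approx(0.916, rel=0.15)


class TestLaplaceAccuracy:
    def test_against_adaptive_gauss_hermite(self):
        """5-node adaptive Gauss-Hermite quadrature (independent of the
        fitting code) agrees with the Laplace OFV within 0.5 units."""
        c = generate(GeneratorConfig(seed=21, n_os_arms=0, n_score_arms=5))
        vals = dict(emax=24.0, et50=16.0, gamma=1.3, eta_sd_emax=0.25,
                    eta_sd_gamma=0.12, eps_sd=4.0)
        ofv_lap = evaluate_ofv(c, "ALSFRS", vals)
        z, w = np.polynomial.hermite.hermgauss(5)
        base = EmaxParams(vals["emax"], vals["et50"], vals["gamma"])
        om = np.array([vals["eta_sd_emax"], vals["eta_sd_gamma"]])

        def arm_nll(arm):
            t = np.array([p.time_months for p in arm.score_series])
            y = np.array([p.mean_change for p in arm.score_series])
            sd = vals["eps_sd"] * np.sqrt(REFERENCE_ARM_SIZE / arm.n)

            def logjoint(eta):
                f = typical_change(t, base, eta)
                return (-0.5 * np.sum((y - f) ** 2) / sd ** 2
                        - t.size * np.log(sd)
                        - 0.5 * t.size * np.log(2 * np.pi)
                        - 0.5 * np.sum((eta / om) ** 2)
                        - np.sum(np.log(om)) - np.log(2 * np.pi))

            res = optimize.minimize(lambda e: -logjoint(e), np.zeros(2),
                                    method="Nelder-Mead",
                                    options={"xatol": 1e-10, "fatol": 1e-12,
                                             "maxiter": 2000})
            m = res.x
            h = 1e-4
            H = np.zeros((2, 2))
            for i in range(2):
                for j in range(2):
                    ei, ej = np.eye(2)[i] * h, np.eye(2)[j] * h
                    H[i, j] = -(logjoint(m + ei + ej) - logjoint(m + ei - ej)
                                - logjoint(m - ei + ej)
                                + logjoint(m - ei - ej)) / (4 * h * h)
            C = np.linalg.inv(H)
            L = np.linalg.cholesky(C)
            tot = 0.0
            for i, zi in enumerate(z):
                for j, zj in enumerate(z):
                    zz = np.array([zi, zj])
                    eta = m + np.sqrt(2.0) * L @ zz
                    tot += w[i] * w[j] * np.exp(logjoint(eta) - logjoint(m)
                                                + zz @ zz)
            return -(logjoint(m) + 0.5 * np.log(np.linalg.det(2.0 * C))
                     + np.log(tot))

        ofv_agh = 2.0 * sum(arm_nll(a) for a in c)
        assert abs(ofv_lap - ofv_agh) < 0.5


class TestBaseHazardSelection:
    def test_single_candidate(self):
        c = generate(GeneratorConfig(seed=700, n_os_arms=12, n_score_arms=0))
        tab = select_base_hazard(c, candidates=("weibull",), n_starts=1)
        assert len(tab) == 1 and tab.base_hazard.iloc[0] == "weibull"

    def test_lognormal_data_prefers_lognormal(self):
        winners = []
        for seed in (700, 701, 702):
            c = generate(GeneratorConfig(seed=seed, n_os_arms=12,
                                         n_score_arms=0))
            winners.append(select_base_hazard(c, n_starts=1)
                           .base_hazard.iloc[0])
        assert winners.count("lognormal") == 3

    def test_exponential_data_ranks_exponential_high(self):
        # hand-built corpus with S = exp(-t/scale), multiplicative study
        # effect on the scale, small logit-scale noise
        rng = np.random.default_rng(8)
        arms = []
        t = np.arange(3.0, 61.0, 3.0)
        for i in range(10):
            scale = 25.0 * np.exp(rng.normal(0.0, 0.15))
            y = to_obs_scale(np.exp(-t / scale), "logit")
            y = y + rng.normal(0.0, 0.1, t.size)
            s = np.minimum.accumulate(1 / (1 + np.exp(-y)))
            cov = CovariateProfile(duration_months=18.0, riluzole_frac=0.9)
            arms.append(StudyArm(f"E{i}", 75, cov,
                                 os_series=tuple(SurvivalPoint(a, b)
                                                 for a, b in zip(t, s))))
        tab = select_base_hazard(Corpus(tuple(arms)), n_starts=1)
        assert "exponential" in list(tab.base_hazard.iloc[:2])


class TestCovariateSearch:
    def test_true_effect_retained_null_dropped(self):
        # strong duration effect on the hazard; male fraction is null
        strong = dc.replace(PLACEBO_OS_PARAMS, theta_duration=0.08)
        c = generate(GeneratorConfig(seed=710, n_os_arms=20, n_score_arms=0,
                                     os_params=strong))
        final, trace = covariate_search(
            c, "OS",
            [CovariateEffect("duration_months", "hazard"),
             CovariateEffect("male_frac", "hazard")],
            n_starts=1, compute_se=False)
        labels = [e.label for e in final.covariate_spec]
        assert "theta_duration" in labels
        assert "theta_male" not in labels
        assert {"step", "covariate", "delta_ofv", "decision"} <= \
            set(trace.columns)

    def test_alsfrs_base_model_retained(self):
        # the generator has no covariate effects on the score parameters
        c = generate(GeneratorConfig(seed=711, n_os_arms=0,
                                     n_score_arms=12))
        final, _ = covariate_search(
            c, "ALSFRS", [CovariateEffect("male_frac", "emax")],
            n_starts=1, compute_se=False)
        assert final.covariate_spec == []

    def test_empty_candidates_equals_fit(self):
        c = generate(GeneratorConfig(seed=712, n_os_arms=0,
                                     n_score_arms=8))
        final, trace = covariate_search(c, "ALSFRS", [], n_starts=1,
                                        compute_se=False)
        direct = fit(c, "ALSFRS", n_starts=1, compute_se=False)
        assert final.ofv == pytest.approx(direct.ofv, abs=1e-6)
        assert trace.empty

    def test_null_covariate_lrt_calibrated(self):
        """Under a null covariate the OFV drop is approximately chi2(1):
        the rejection rate at 3.84 stays near its nominal 5% level."""
        dofv = []
        for seed in range(30):
            c = generate(GeneratorConfig(seed=500 + seed, n_os_arms=0,
                                         n_score_arms=12))
            b = fit(c, "ALSFRS", n_starts=1, compute_se=False)
            a = fit(c, "ALSFRS",
                    covariate_spec=[CovariateEffect("male_frac", "emax")],
                    n_starts=1, compute_se=False)
            dofv.append(b.ofv - a.ofv)
        dofv = np.array(dofv)
        assert np.mean(dofv > 3.84) <= 0.2
        assert 0.0 <= np.median(dofv) < 2.5


class TestEmpiricalBayes:
    def test_shrinkage_toward_zero(self):
        c = generate(GeneratorConfig(seed=21, n_os_arms=0, n_score_arms=8))
        r = fit(c, "ALSFRS", n_starts=2, compute_se=False)
        base = EmaxParams(r.estimates["emax"], r.estimates["et50"],
                          r.estimates["gamma"])
        for arm in c:
            t = np.array([p.time_months for p in arm.score_series])
            y = np.array([p.mean_change for p in arm.score_series])
            mle = optimize.minimize(
                lambda e: 0.5 * np.sum((y - typical_change(t, base, e)) ** 2),
                np.zeros(2), method="Nelder-Mead").x
            ehat = np.array(r.eb_effects[arm.study_id]["eta"])
            # penalized modes are pulled toward zero; compare norms since
            # the two components are coupled through the curve shape
            assert np.linalg.norm(ehat) <= np.linalg.norm(mle) + 1e-6

    def test_conditional_se_decreases_with_more_observations(self):
        rng = np.random.default_rng(4)
        P = PLACEBO_EMAX_PARAMS
        arms = []
        for i, horizon in enumerate([12.0, 12.0, 12.0, 48.0, 48.0, 48.0]):
            t = np.arange(3.0, horizon + 1e-9, 3.0)
            y = typical_change(t, P) + rng.normal(0, 1.0, t.size)
            cov = CovariateProfile(duration_months=18.0, riluzole_frac=0.9)
            arms.append(StudyArm(f"S{i}", 75, cov,
                                 score_series=tuple(
                                     ScorePoint(a, float(np.clip(b, -48, 48)))
                                     for a, b in zip(t, y))))
        r = fit(Corpus(tuple(arms)), "ALSFRS", n_starts=2, compute_se=False)
        short = np.mean([r.eb_effects[f"S{i}"]["cond_sd"][0]
                         for i in range(3)])
        long = np.mean([r.eb_effects[f"S{i}"]["cond_sd"][0]
                        for i in range(3, 6)])
        assert long < short

    def test_table_structure(self, alsfrs_fit, default_corpus):
        eb = empirical_bayes(alsfrs_fit, default_corpus)
        assert len(eb) == alsfrs_fit.n_arms
        assert {"study_id", "emax", "gamma", "se_emax", "se_gamma"} <= \
            set(eb.columns)
        # study-level parameter is base estimate scaled by exp(eta)
        row = eb.iloc[0]
        assert row["emax"] == pytest.approx(
            alsfrs_fit.estimates["emax"] * np.exp(row["eta_emax"]),
            rel=1e-9)


class TestBootstrap:
    def _small_corpus(self):
        return generate(GeneratorConfig(seed=31, n_os_arms=0,
                                        n_score_arms=8))

    def test_single_resample_deterministic(self):
        c = self._small_corpus()
        base = fit(c, "ALSFRS", n_starts=1)
        b1 = bootstrap(c, "ALSFRS", n_reps=1, seed=9, base_fit=base)
        b2 = bootstrap(c, "ALSFRS", n_reps=1, seed=9, base_fit=base)
        assert b1.median == b2.median

    def test_identical_arms_degenerate_interval(self):
        arm = self._small_corpus().arms[0]
        clones = Corpus(tuple(dc.replace(arm, study_id=f"C{i}")
                              for i in range(3)))
        base = fit(clones, "ALSFRS", n_starts=1)
        b = bootstrap(clones, "ALSFRS", n_reps=5, seed=0, base_fit=base)
        for lo, hi in b.ci95.values():
            assert hi - lo < 1e-6

    def test_success_counting_and_medians(self):
        c = self._small_corpus()
        base = fit(c, "ALSFRS", n_starts=2)
        b = bootstrap(c, "ALSFRS", n_reps=20, seed=3, base_fit=base)
        assert b.n_success <= b.n_attempted == 20
        assert b.n_success >= 10
        assert set(b.median) == set(base.estimates)


class TestFitContracts:
    def test_too_few_arms_rejected(self):
        c = generate(GeneratorConfig(seed=1, n_os_arms=2, n_score_arms=3))
        with pytest.raises(ValueError, match=">= 3 arms"):
            fit(c, "OS")

    def test_unknown_endpoint_rejected(self, default_corpus):
        with pytest.raises(ValueError):
            fit(default_corpus, "PFS")

    def test_params_object_roundtrip(self, alsfrs_fit, os_fit):
        p = alsfrs_fit.params
        assert isinstance(p, EmaxParams)
        assert p.emax == alsfrs_fit.estimates["emax"]
        q = os_fit.params
        assert q.theta_duration == os_fit.estimates["theta_duration"]
        assert q.duration_center == 17.8
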