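"""External-control comparison and Bayesian borrowing: the printed
talampanel numbers, conjugate identities, and an MCMC cross-check."""

import numpy as np
import pytest

from alsmbma.trial_data import CovariateProfile, ScorePoint, SurvivalPoint
from alsmbma.alsfrs_model import typical_change
from alsmbma.os_model import survival
from alsmbma.reference import (PLACEBO_EMAX_PARAMS, PLACEBO_EMAX_RSE,
                               PLACEBO_OS_PARAMS)
from alsmbma.application import (ArmSummary, borrow_report, ci_to_se,
                                 conjugate_update, external_control_compare)
from alsmbma.synthetic_data import GeneratorConfig, generate_single_arm_trial

PRIOR = ArmSummary(-8.07, -9.57, -6.72)
OBSERVED = ArmSummary(-10.1, -12.75, -7.45)
DRUG = ArmSummary(-7.1, -9.04, -5.16)


class TestCiToSe:
    @pytest.mark.parametrize("lo,hi,expected", [
        (-9.57, -6.72, 0.727),
        (-12.75, -7.45, 1.352),
        (-1.959963984540054, 1.959963984540054, 1.0),
    ])
    def test_width_conversion(self, lo, hi, expected):
        assert ci_to_se(lo, hi) == pytest.approx(expected, abs=0.001)

    def test_degenerate_interval_rejected(self):
        with pytest.raises(ValueError):
            ci_to_se(1.0, 1.0)


class TestConjugateUpdate:
    def test_published_posterior(self):
        post = conjugate_update(PRIOR, OBSERVED)
        assert post.mean == pytest.approx(-8.53, abs=0.02)
        assert post.lo95 == pytest.approx(-9.79, abs=0.02)
        assert post.hi95 == pytest.approx(-7.27, abs=0.02)

    def test_flat_prior_limit_returns_observation(self):
        flat = ArmSummary(0.0, -1e6, 1e6)
        post = conjugate_update(flat, OBSERVED)
        assert post.mean == pytest.approx(OBSERVED.mean, abs=1e-4)
        assert post.sd == pytest.approx(OBSERVED.se, rel=1e-4)

    def test_equal_precision_halves_variance(self):
        post = conjugate_update(OBSERVED, OBSERVED)
        assert post.mean == OBSERVED.mean
        assert post.sd == pytest.approx(OBSERVED.se / np.sqrt(2.0),
                                        rel=1e-12)

    def test_posterior_mean_between_inputs(self):
        post = conjugate_update(PRIOR, OBSERVED)
        lo, hi = sorted([PRIOR.mean, OBSERVED.mean])
        assert lo < post.mean < hi

    def test_posterior_sd_below_both(self):
        post = conjugate_update(PRIOR, OBSERVED)
        assert post.sd < min(PRIOR.se, OBSERVED.se)

    def test_borrow_weight_is_prior_precision_share(self):
        post = conjugate_update(PRIOR, OBSERVED)
        expected = (PRIOR.se ** -2) / (PRIOR.se ** -2 + OBSERVED.se ** -2)
        assert post.borrow_weight == pytest.approx(expected, rel=1e-12)

    def test_metropolis_crosscheck(self):
        """A random-walk Metropolis sampler on the same normal likelihood x
        normal prior reproduces the conjugate posterior within 1%."""
        rng = np.random.default_rng(12345)
        post = conjugate_update(PRIOR, OBSERVED)

        def logp(th):
            return (-0.5 * ((th - PRIOR.mean) / PRIOR.se) ** 2
                    - 0.5 * ((th - OBSERVED.mean) / OBSERVED.se) ** 2)

        n = 50_000
        draws = np.empty(n)
        th = PRIOR.mean
        lp = logp(th)
        for i in range(n):
            prop = th + rng.normal(0.0, 1.2)
            lp_prop = logp(prop)
            if np.log(rng.uniform()) < lp_prop - lp:
                th, lp = prop, lp_prop
            draws[i] = th
        draws = draws[5000:]
        assert np.mean(draws) == pytest.approx(post.mean, rel=0.01)
        assert np.std(draws) == pytest.approx(post.sd, rel=0.05)


class TestBorrowReport:
    def test_published_relative_efficacy(self):
        post = conjugate_update(PRIOR, OBSERVED)
        rep = borrow_report(post, DRUG)
        assert rep["pct_lower_than_placebo"] == pytest.approx(17.0, abs=1.0)

    def test_no_borrowing_comparison(self):
        # flat prior -> posterior equals the concurrent placebo arm, so the
        # report reduces to the unborrowed -10.1 vs -7.1 comparison
        flat = ArmSummary(0.0, -1e6, 1e6)
        rep = borrow_report(conjugate_update(flat, OBSERVED), DRUG)
        assert rep["pct_lower_than_placebo"] == pytest.approx(30.0, abs=1.0)

    def test_equal_means_zero_percent(self):
        post = conjugate_update(PRIOR, OBSERVED)
        same = ArmSummary(post.mean, post.lo95, post.hi95)
        rep = borrow_report(post, same)
        assert rep["pct_lower_than_placebo"] == pytest.approx(0.0, abs=1e-9)


class TestExternalControl:
    COV = CovariateProfile(duration_months=19.2, riluzole_frac=0.72)

    def test_typical_series_inside_band(self):
        t = np.array([3.0, 6.0, 9.0, 12.0])
        series = [ScorePoint(ti, float(typical_change(ti,
                                                      PLACEBO_EMAX_PARAMS)))
                  for ti in t]
        se = {k: abs(getattr(PLACEBO_EMAX_PARAMS, k)) * v / 100
              for k, v in PLACEBO_EMAX_RSE.items()}
        res = external_control_compare(PLACEBO_EMAX_PARAMS, self.COV, series,
                                       endpoint="ALSFRS", n_mc=400, seed=0,
                                       se=se)
        assert (res["per_point"].verdict == "inside").all()
        assert res["verdict"] == "no difference"

    def test_series_below_band_is_inferior(self):
        # lithium-carbonate pattern: survival uniformly below the band
        t = np.array([4.0, 8.0, 12.0, 16.0])
        s = survival(t, self.COV, PLACEBO_OS_PARAMS) * 0.05
        series = [SurvivalPoint(ti, float(si)) for ti, si in zip(t, s)]
        res = external_control_compare(PLACEBO_OS_PARAMS, self.COV, series,
                                       endpoint="OS", n_mc=400, seed=0)
        assert res["verdict"] == "inferior"
        assert (res["per_point"].verdict == "below").all()

    def test_score_above_band_is_superior(self):
        # constructed: every point lies above the band (here the band is
        # collapsed to the typical curve, so "above" means less decline)
        t = np.array([3.0, 6.0, 9.0, 12.0])
        series = [ScorePoint(ti, -0.05) for ti in t]
        res = external_control_compare(PLACEBO_EMAX_PARAMS, self.COV, series,
                                       endpoint="ALSFRS", n_mc=100, seed=0,
                                       include_eta=False, include_eps=False)
        assert (res["per_point"].verdict == "above").all()
        assert res["verdict"] == "superior"

    def test_placebo_like_arm_calibration(self):
        """Arms generated at effect = 1 stay inside the predictive band at
        >= 90% of points on average over seeds."""
        fracs = []
        for seed in range(10):
            trial = generate_single_arm_trial(GeneratorConfig(seed=200 + seed),
                                              effect=1.0, endpoint="OS")
            res = external_control_compare(
                PLACEBO_OS_PARAMS, trial.covariates, trial.os_series,
                endpoint="OS", n_mc=300, seed=3, arm_n=trial.n)
            fracs.append((res["per_point"].verdict == "inside").mean())
        assert np.mean(fracs) >= 0.90

    def test_strong_hazard_effect_lifts_late_points(self):
        # typical phase-II/III arm sizes: small arms cannot beat the
        # width of their own predictive band
        hits = 0
        for seed in range(8):
            cfg = GeneratorConfig(seed=300 + seed, n_range=(100, 300))
            trial = generate_single_arm_trial(cfg, effect=0.4, endpoint="OS")
            res = external_control_compare(
                PLACEBO_OS_PARAMS, trial.covariates, trial.os_series,
                endpoint="OS", n_mc=300, seed=3, arm_n=trial.n)
            late = res["per_point"].iloc[-7:]
            hits += int((late.verdict == "above").sum() >= 3)
        assert hits >= 4


class TestArmSummary:
    def test_invalid_interval_rejected(self):
        with pytest.raises(ValueError):
            ArmSummary(0.0, 1.0, 2.0)
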