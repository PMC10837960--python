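"""Nonlinear mixed-effects estimation on aggregate arm-level data.

Marginal maximum likelihood with study-level random effects, in the style of
pharmacometric meta-analysis: per arm, observations on the fitting scale are
normal around the structural prediction given the arm's random effects eta;
eta ~ N(0, diag(omega^2)) acts multiplicatively (log-normally) on structural
parameters; the residual SD of an arm of size n is sigma * sqrt(75/n). The
marginal likelihood is approximated by Laplace's method with a Gauss-Newton
(first-order-conditional style) Hessian at the per-arm posterior mode of eta.

OFV is -2 log marginal likelihood, including normalization constants, so
likelihood-ratio differences between nested models are chi-squared.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace as dc_replace
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit, ndtr, ndtri

from .trial_data import Corpus, StudyArm
from . import os_model, alsfrs_model
from .os_model import OSParams, to_obs_scale
from .alsfrs_model import EmaxParams, REFERENCE_ARM_SIZE

__all__ = ["CovariateEffect", "FitResult", "BootstrapResult", "fit",
           "select_base_hazard", "covariate_search", "empirical_bayes",
           "bootstrap", "os_final_covariates", "evaluate_ofv"]

logger = logging.getLogger(__name__)


def _safe_exp(v):
    return np.exp(np.clip(v, -30.0, 30.0))

# Forward-inclusion / backward-elimination OFV thresholds (chi2_1 at p<.05/.01)
FORWARD_DOFV = 3.84
BACKWARD_DOFV = 6.63

_OMEGA_MIN = 1e-3

#: Short report labels for covariate fields.
_COV_SHORT = {
    "duration_months": "duration", "riluzole_frac": "riluzole",
    "age_onset_years": "age_onset", "male_frac": "male",
    "bulbar_frac": "bulbar", "baseline_alsfrs": "baseline",
    "basic_treatment": "basic_treatment", "pub_year": "pub_year",
}

# struct parameter names, outer transforms, and random-effect-bearing params
_HAZARDS = {
    "lognormal": (("mu", "sigm"), ("raw", "log"), ("sigm", "mu")),
    "weibull": (("wb_scale", "wb_shape"), ("log", "log"),
                ("wb_scale", "wb_shape")),
    "loglogistic": (("ll_scale", "ll_shape"), ("log", "log"),
                    ("ll_scale", "ll_shape")),
    "exponential": (("exp_scale",), ("log",), ("exp_scale",)),
}


@dataclass(frozen=True)
class CovariateEffect:
    """One candidate covariate effect.

    ``target`` is "hazard" for the OS proportional-hazards linear predictor,
    or a structural parameter name (emax/et50/gamma) for the score model,
    where the effect acts additively on the log-parameter. ``center`` None
    means "center at the corpus median"; 0.0 means uncentered.
    """

    name: str
    target: str = "hazard"
    center: Optional[float] = None

    @property
    def label(self) -> str:
        short = _COV_SHORT.get(self.name, self.name)
        return (f"theta_{short}" if self.target == "hazard"
                else f"theta_{short}_{self.target}")


def os_final_covariates() -> list:
    """The published OS covariate structure: duration (centered at 17.8
    months) and riluzole fraction (uncentered) on the log-hazard."""
    return [CovariateEffect("duration_months", "hazard", 17.8),
            CovariateEffect("riluzole_frac", "hazard", 0.0)]


@dataclass
class _Design:
    """Flattened observation arrays for one endpoint of a corpus."""

    endpoint: str
    t: np.ndarray
    y: np.ndarray
    arm_idx: np.ndarray
    arm_ids: list
    arm_n: np.ndarray
    m_per_arm: np.ndarray
    res_w: np.ndarray        # per-arm residual multiplier sqrt(75/n)
    cov_x: np.ndarray        # (A, C) centered covariate values
    effects: list            # resolved CovariateEffect (centers filled in)
    obs_scale: str
    n_dropped: int = 0

    @property
    def n_arms(self) -> int:
        return len(self.arm_ids)


def _build_design(corpus: Corpus, endpoint: str,
                  covariate_spec: Sequence[CovariateEffect],
                  obs_scale: str) -> _Design:
    sub = corpus.subset(endpoint)
    arms, dropped = [], 0
    for arm in sub:
        if any(arm.covariates.get(e.name) is None for e in covariate_spec):
            dropped += 1
            continue
        arms.append(arm)
    if dropped:
        logger.info("dropped %d arm(s) missing a requested covariate", dropped)
    if len(arms) < 3:
        raise ValueError(f"need >= 3 arms with endpoint {endpoint}, "
                         f"have {len(arms)}")

    t, y, idx = [], [], []
    for i, arm in enumerate(arms):
        if endpoint == "OS":
            tt = [p.time_months for p in arm.os_series]
            yy = to_obs_scale([p.surv_prob for p in arm.os_series], obs_scale)
        else:
            tt = [p.time_months for p in arm.score_series]
            yy = [p.mean_change for p in arm.score_series]
        t.extend(tt)
        y.extend(np.asarray(yy, dtype=float))
        idx.extend([i] * len(tt))
    arm_n = np.array([a.n for a in arms], dtype=float)

    effects, cols = [], []
    for e in covariate_spec:
        vals = np.array([float(a.covariates.get(e.name)) for a in arms])
        center = float(np.median(vals)) if e.center is None else e.center
        effects.append(dc_replace(e, center=center))
        cols.append(vals - center)
    cov_x = (np.column_stack(cols) if cols
             else np.zeros((len(arms), 0)))
    arm_idx = np.asarray(idx, dtype=np.intp)
    return _Design(endpoint=endpoint, t=np.asarray(t, float),
                   y=np.asarray(y, float), arm_idx=arm_idx,
                   arm_ids=[a.study_id for a in arms], arm_n=arm_n,
                   m_per_arm=np.bincount(arm_idx, minlength=len(arms)).astype(float),
                   res_w=np.sqrt(REFERENCE_ARM_SIZE / arm_n),
                   cov_x=cov_x, effects=effects, obs_scale=obs_scale,
                   n_dropped=dropped)


class _ParamMap:
    """Packs/unpacks the outer optimization vector.

    Layout: structural params (log-transformed where positive), covariate
    thetas (raw), log between-study SDs, log residual SD.
    """

    def __init__(self, endpoint: str, base_hazard: str, effects: list):
        self.endpoint = endpoint
        self.base_hazard = base_hazard
        if endpoint == "OS":
            struct, trans, eta_on = _HAZARDS[base_hazard]
        else:
            struct, trans, eta_on = (("emax", "et50", "gamma"),
                                     ("log", "log", "log"), ("emax", "gamma"))
        self.struct = list(struct)
        self.trans = list(trans)
        self.eta_on = list(eta_on)
        self.theta_labels = [e.label for e in effects]
        self.names = (self.struct + self.theta_labels
                      + [f"eta_sd_{p}" for p in self.eta_on] + ["eps_sd"])
        self.n_struct = len(self.struct)
        self.n_theta = len(self.theta_labels)
        self.n_eta = len(self.eta_on)

    def pack(self, natural: dict) -> np.ndarray:
        x = []
        for p, tr in zip(self.struct, self.trans):
            v = natural[p]
            x.append(np.log(v) if tr == "log" else v)
        x += [natural.get(l, 0.0) for l in self.theta_labels]
        x += [np.log(max(natural[f"eta_sd_{p}"], _OMEGA_MIN))
              for p in self.eta_on]
        x.append(np.log(max(natural["eps_sd"], 1e-4)))
        return np.asarray(x, float)

    def unpack(self, x: np.ndarray):
        ns, nt, ne = self.n_struct, self.n_theta, self.n_eta
        struct = {}
        for p, tr, v in zip(self.struct, self.trans, x[:ns]):
            struct[p] = float(np.exp(v)) if tr == "log" else float(v)
        thetas = np.asarray(x[ns:ns + nt], float)
        omegas = np.exp(np.asarray(x[ns + nt:ns + nt + ne], float))
        sigma = float(np.exp(x[ns + nt + ne]))
        return struct, thetas, omegas, sigma

    def natural(self, x: np.ndarray) -> dict:
        struct, thetas, omegas, sigma = self.unpack(x)
        out = dict(struct)
        out.update(dict(zip(self.theta_labels, thetas)))
        out.update({f"eta_sd_{p}": o for p, o in zip(self.eta_on, omegas)})
        out["eps_sd"] = sigma
        return out

    def jac_natural(self, x: np.ndarray) -> np.ndarray:
        """d(natural)/d(x) per parameter (diagonal), for delta-method SEs."""
        nat = self.natural(x)
        jac = []
        for i, name in enumerate(self.names):
            tr = (self.trans[i] if i < self.n_struct
                  else ("raw" if i < self.n_struct + self.n_theta else "log"))
            jac.append(1.0 if tr == "raw" else abs(nat[name]))
        return np.asarray(jac)

    def bounds(self):
        b = []
        for p, tr in zip(self.struct, self.trans):
            b.append((-5.0, 8.0) if tr == "raw" else (np.log(1e-3), np.log(1e3)))
        b += [(-10.0, 10.0)] * self.n_theta
        b += [(np.log(_OMEGA_MIN), np.log(3.0))] * self.n_eta
        b.append((np.log(1e-4), np.log(50.0)))
        return b


def _make_predictor(pmap: _ParamMap, design: _Design, struct: dict,
                    thetas: np.ndarray) -> Callable[[np.ndarray], np.ndarray]:
    """Build f(eta) -> predictions on the fitting scale for all observations."""
    t, arm_idx = design.t, design.arm_idx
    if pmap.endpoint == "OS":
        lp = design.cov_x @ thetas if pmap.n_theta else np.zeros(design.n_arms)
        hr = np.exp(lp)[arm_idx]
        scale = design.obs_scale
        hz = pmap.base_hazard
        logt = np.log(t)
        if hz == "lognormal":
            mu, sigm = struct["mu"], struct["sigm"]

            def pred(eta):
                sigm_i = np.maximum(sigm * _safe_exp(eta[:, 0]), 1e-8)
                mu_i = mu * _safe_exp(eta[:, 1])
                z = (logt - mu_i[arm_idx]) / sigm_i[arm_idx]
                return to_obs_scale(ndtr(-z) ** hr, scale)
        elif hz == "weibull":
            sc, sh = struct["wb_scale"], struct["wb_shape"]

            def pred(eta):
                sc_i = np.maximum(sc * _safe_exp(eta[:, 0]), 1e-8)
                sh_i = np.minimum(sh * _safe_exp(eta[:, 1]), 50.0)
                s0 = np.exp(-np.minimum((t / sc_i[arm_idx]) ** sh_i[arm_idx],
                                        700.0))
                return to_obs_scale(s0 ** hr, scale)
        elif hz == "loglogistic":
            sc, sh = struct["ll_scale"], struct["ll_shape"]

            def pred(eta):
                sc_i = np.maximum(sc * _safe_exp(eta[:, 0]), 1e-8)
                sh_i = np.minimum(sh * _safe_exp(eta[:, 1]), 50.0)
                s0 = expit(-sh_i[arm_idx] * (logt - np.log(sc_i[arm_idx])))
                return to_obs_scale(s0 ** hr, scale)
        elif hz == "exponential":
            sc = struct["exp_scale"]

            def pred(eta):
                sc_i = np.maximum(sc * _safe_exp(eta[:, 0]), 1e-8)
                return to_obs_scale(np.exp(-t / sc_i[arm_idx]) ** hr, scale)
        else:
            raise ValueError(f"unknown base hazard {hz!r}")
        return pred

    # ALSFRS: covariates act on log structural parameters
    shifts = {p: np.zeros(design.n_arms) for p in ("emax", "et50", "gamma")}
    for j, e in enumerate(design.effects):
        shifts[e.target] = shifts[e.target] + thetas[j] * design.cov_x[:, j]
    emax, et50, gamma = struct["emax"], struct["et50"], struct["gamma"]
    sh_emax, sh_et50, sh_gamma = (shifts["emax"], shifts["et50"],
                                  shifts["gamma"])

    logt = np.log(t)

    def pred(eta):
        # t^g / (ET50^g + t^g) = expit(g * (log t - log ET50)): overflow-safe
        emax_i = (emax * _safe_exp(sh_emax + eta[:, 0]))[design.arm_idx]
        gamma_i = (gamma * _safe_exp(sh_gamma + eta[:, 1]))[design.arm_idx]
        log_et50_i = (np.log(et50) + sh_et50)[design.arm_idx]
        return -emax_i * expit(gamma_i * (logt - log_et50_i))

    return pred


def _inner_laplace(pred, design: _Design, omegas: np.ndarray, sigma: float,
                   eta0: np.ndarray, tol: float = 1e-9, max_iter: int = 40):
    """Per-arm posterior modes of eta by damped Gauss-Newton, vectorized.

    Returns (eta_hat, q, Amat, r): q is the per-arm penalized half-RSS, Amat
    the per-arm Gauss-Newton information G' Sigma^-1 G.
    """
    A, d = design.n_arms, omegas.size
    y, arm_idx = design.y, design.arm_idx
    sd_arm = sigma * design.res_w
    inv_sd2 = 1.0 / sd_arm ** 2
    invw2 = 1.0 / omegas ** 2
    eta = eta0.copy()

    def qfun(e):
        r = y - pred(e)
        rss = np.bincount(arm_idx, weights=r * r, minlength=A)
        return 0.5 * rss * inv_sd2 + 0.5 * (e ** 2 * invw2).sum(axis=1), r

    q, r = qfun(eta)
    h = 1e-5
    Amat = None
    for _ in range(max_iter):
        G = np.empty((y.size, d))
        for k in range(d):
            ep = eta.copy(); ep[:, k] += h
            em = eta.copy(); em[:, k] -= h
            G[:, k] = (pred(ep) - pred(em)) / (2 * h)
        Amat = np.empty((A, d, d))
        b = np.empty((A, d))
        for k in range(d):
            b[:, k] = np.bincount(arm_idx, weights=G[:, k] * r,
                                  minlength=A) * inv_sd2
            for l in range(k, d):
                s = np.bincount(arm_idx, weights=G[:, k] * G[:, l],
                                minlength=A) * inv_sd2
                Amat[:, k, l] = s
                Amat[:, l, k] = s
        H = Amat.copy()
        H[:, np.arange(d), np.arange(d)] += invw2
        grad = -b + eta * invw2
        try:
            step = np.linalg.solve(H, -grad[:, :, None])[:, :, 0]
        except np.linalg.LinAlgError:
            H[:, np.arange(d), np.arange(d)] += 1e-8
            step = np.linalg.solve(H, -grad[:, :, None])[:, :, 0]
        scale = np.ones(A)
        for _bt in range(6):
            q_new, r_new = qfun(eta + step * scale[:, None])
            worse = q_new > q + 1e-12
            if not worse.any():
                break
            scale[worse] *= 0.5
        accept = q_new <= q + 1e-12
        eta = np.where(accept[:, None], eta + step * scale[:, None], eta)
        eta = np.clip(eta, -15.0, 15.0)
        q = np.where(accept, q_new, q)
        _, r = qfun(eta)
        if np.max(np.abs(step * scale[:, None])) < tol:
            break
    # refresh curvature at the final mode
    G = np.empty((y.size, d))
    for k in range(d):
        ep = eta.copy(); ep[:, k] += h
        em = eta.copy(); em[:, k] -= h
        G[:, k] = (pred(ep) - pred(em)) / (2 * h)
    Amat = np.empty((A, d, d))
    for k in range(d):
        for l in range(k, d):
            s = np.bincount(arm_idx, weights=G[:, k] * G[:, l],
                            minlength=A) * inv_sd2
            Amat[:, k, l] = s
            Amat[:, l, k] = s
    return eta, q, Amat, r


def _ofv_terms(design: _Design, omegas, sigma, q, Amat):
    """OFV = 2 * sum of per-arm Laplace negative log marginal likelihoods."""
    d = omegas.size
    sd_arm = sigma * design.res_w
    M = omegas[None, :, None] ** 2 * Amat
    M[:, np.arange(d), np.arange(d)] += 1.0
    dets = np.linalg.det(M)
    dets = np.maximum(dets, 1e-300)
    nll = (q + design.m_per_arm * np.log(sd_arm)
           + 0.5 * design.m_per_arm * np.log(2 * np.pi)
           + 0.5 * np.log(dets))
    return 2.0 * float(nll.sum())


@dataclass
class FitResult:
    """Converged estimates, uncertainties and per-study random effects."""

    estimates: dict
    se: dict
    rse_pct: dict
    ofv: float
    eb_effects: dict          # study_id -> {"eta": tuple, "cond_sd": tuple}
    converged: bool
    n_arms: int
    endpoint: str
    base_hazard: str
    covariate_spec: list
    obs_scale: str
    x_opt: np.ndarray = field(repr=False, default=None)
    names: list = field(repr=False, default=None)
    hessian_finite: Optional[bool] = None

    @property
    def n_params(self) -> int:
        return len(self.estimates)

    @property
    def aic(self) -> float:
        return self.ofv + 2 * self.n_params

    @property
    def params(self):
        """Typed parameter object for the canonical model configurations."""
        e = self.estimates
        if self.endpoint == "ALSFRS" and not self.covariate_spec:
            return EmaxParams(emax=e["emax"], et50=e["et50"], gamma=e["gamma"],
                              eta_sd_emax=e["eta_sd_emax"],
                              eta_sd_gamma=e["eta_sd_gamma"],
                              eps_sd=e["eps_sd"])
        if self.endpoint == "OS" and self.base_hazard == "lognormal":
            th_d = e.get("theta_duration", 0.0)
            th_r = e.get("theta_riluzole", 0.0)
            center = 17.8
            for eff in self.covariate_spec:
                if eff.name == "duration_months" and eff.center is not None:
                    center = eff.center
            return OSParams(mu=e["mu"], sigm=e["sigm"], theta_duration=th_d,
                            theta_riluzole=th_r, duration_center=center,
                            eta_sd_sigm=e["eta_sd_sigm"],
                            eta_sd_mu=e["eta_sd_mu"], eps_sd=e["eps_sd"],
                            obs_scale=self.obs_scale)
        return None

    def to_json_dict(self) -> dict:
        return {"endpoint": self.endpoint, "base_hazard": self.base_hazard,
                "estimates": self.estimates, "se": self.se,
                "rse_pct": self.rse_pct, "ofv": self.ofv,
                "converged": self.converged, "n_arms": self.n_arms}


@dataclass
class BootstrapResult:
    """Study-level nonparametric bootstrap summary."""

    n_attempted: int
    n_success: int
    median: dict
    ci95: dict
    replicates: pd.DataFrame = field(repr=False, default=None)


def _starting_values(design: _Design, pmap: _ParamMap) -> dict:
    t, y = design.t, design.y
    nat = {}
    if pmap.endpoint == "OS":
        s = os_model.from_obs_scale(y, design.obs_scale)
        s = np.clip(s, 1e-6, 1 - 1e-6)
        logt = np.log(t)
        if pmap.base_hazard == "lognormal":
            qq = -ndtri(s)                      # Phi^-1(1 - S)
            slope, inter = np.polyfit(qq, logt, 1)
            nat["mu"] = float(inter)
            nat["sigm"] = float(max(slope, 0.05))
        elif pmap.base_hazard == "weibull":
            cll = np.log(-np.log(s))
            slope, inter = np.polyfit(logt, cll, 1)
            slope = max(slope, 0.05)
            nat["wb_shape"] = float(slope)
            nat["wb_scale"] = float(np.exp(-inter / slope))
        elif pmap.base_hazard == "loglogistic":
            lg = np.log((1 - s) / s)
            slope, inter = np.polyfit(logt, lg, 1)
            slope = max(slope, 0.05)
            nat["ll_shape"] = float(slope)
            nat["ll_scale"] = float(np.exp(-inter / slope))
        else:
            nat["exp_scale"] = float(np.mean(t / np.maximum(-np.log(s), 1e-6)))
        sigma0 = 0.4
    else:
        try:
            def f(tt, e, l50, g):
                return -e * tt ** g / (l50 ** g + tt ** g)
            p0, _ = optimize.curve_fit(f, t, y, p0=(15.0, 15.0, 1.2),
                                       bounds=([1, 1, 0.2], [48, 120, 8]),
                                       maxfev=5000)
            nat.update(emax=float(p0[0]), et50=float(p0[1]), gamma=float(p0[2]))
        except Exception:
            nat.update(emax=max(1.2 * float(-y.min()), 5.0), et50=15.0,
                       gamma=1.2)
        sigma0 = max(0.3, float(np.std(y)) / 3)
    for lab in pmap.theta_labels:
        nat[lab] = 0.0
    for p in pmap.eta_on:
        nat[f"eta_sd_{p}"] = 0.15
    nat["eps_sd"] = sigma0
    return nat


def _make_objective(design: _Design, pmap: _ParamMap):
    eta_ws = {"eta": np.zeros((design.n_arms, pmap.n_eta))}

    def nll(x):
        struct, thetas, omegas, sigma = pmap.unpack(x)
        pred = _make_predictor(pmap, design, struct, thetas)
        eta, q, Amat, _ = _inner_laplace(pred, design, omegas, sigma,
                                         eta_ws["eta"])
        eta_ws["eta"] = eta
        ofv = _ofv_terms(design, omegas, sigma, q, Amat)
        if not np.isfinite(ofv):
            return 1e10
        return 0.5 * ofv

    return nll, eta_ws


def _hessian(fun, x, rel_step=1e-4):
    n = x.size
    h = rel_step * (1.0 + np.abs(x))
    H = np.empty((n, n))
    f0 = fun(x)
    for i in range(n):
        for j in range(i, n):
            if i == j:
                xp = x.copy(); xp[i] += h[i]
                xm = x.copy(); xm[i] -= h[i]
                H[i, i] = (fun(xp) - 2 * f0 + fun(xm)) / h[i] ** 2
            else:
                xpp = x.copy(); xpp[[i, j]] += [h[i], h[j]]
                xpm = x.copy(); xpm[i] += h[i]; xpm[j] -= h[j]
                xmp = x.copy(); xmp[i] -= h[i]; xmp[j] += h[j]
                xmm = x.copy(); xmm[[i, j]] -= [h[i], h[j]]
                H[i, j] = H[j, i] = ((fun(xpp) - fun(xpm) - fun(xmp) + fun(xmm))
                                     / (4 * h[i] * h[j]))
    return H


def fit(corpus: Corpus, endpoint: str = "OS",
        base_hazard: str = "lognormal",
        covariate_spec: Optional[Sequence[CovariateEffect]] = None,
        obs_scale: str = "logit", n_starts: int = 5, seed: int = 0,
        x0: Optional[np.ndarray] = None,
        compute_se: bool = True) -> FitResult:
    """Fit the structural + random-effects model to one endpoint.

    ``covariate_spec`` defaults to the base (covariate-free) model; pass
    :func:`os_final_covariates` for the published OS covariate structure.
    ``n_starts`` jittered restarts guard against local optima; ``x0`` (on
    the internal transformed scale) overrides the data-driven start, which
    is the usual warm start for bootstrap refits.
    """
    if endpoint not in ("OS", "ALSFRS"):
        raise ValueError(f"unknown endpoint {endpoint!r}")
    if endpoint == "ALSFRS":
        base_hazard = "emax"  # structural model label; no hazard involved
    covariate_spec = list(covariate_spec or [])
    design = _build_design(corpus, endpoint, covariate_spec, obs_scale)
    pmap = _ParamMap(endpoint, base_hazard, design.effects)
    nll, eta_ws = _make_objective(design, pmap)

    if x0 is None:
        x0 = pmap.pack(_starting_values(design, pmap))
    rng = np.random.default_rng(seed)
    bounds = pmap.bounds()
    best = None
    for s in range(max(1, n_starts)):
        xs = x0 if s == 0 else x0 + rng.normal(0.0, 0.2, size=x0.size)
        xs = np.clip(xs, [b[0] for b in bounds], [b[1] for b in bounds])
        eta_ws["eta"][:] = 0.0
        try:
            res = optimize.minimize(nll, xs, method="L-BFGS-B", bounds=bounds,
                                    options={"maxiter": 400, "ftol": 1e-12,
                                             "gtol": 1e-7, "eps": 1e-6})
        except (FloatingPointError, np.linalg.LinAlgError):
            continue
        if best is None or res.fun < best.fun - 1e-9:
            best = res
    if best is None:
        raise RuntimeError("all optimization starts failed")

    x_opt = best.x
    ofv = 2.0 * float(best.fun)
    converged = bool(best.success)

    nat = pmap.natural(x_opt)
    se = {k: np.nan for k in pmap.names}
    rse = {k: np.nan for k in pmap.names}
    hessian_finite = None
    if compute_se:
        try:
            H = _hessian(nll, x_opt)
            hessian_finite = bool(np.all(np.isfinite(H)))
            cov = np.linalg.inv(H)
            dvar = np.diag(cov)
            if np.all(np.isfinite(dvar)) and np.all(dvar > 0):
                se_x = np.sqrt(dvar)
                se_nat = se_x * pmap.jac_natural(x_opt)
                for k, s_ in zip(pmap.names, se_nat):
                    se[k] = float(s_)
                    rse[k] = float(100.0 * s_ / abs(nat[k])) if nat[k] else np.nan
        except np.linalg.LinAlgError:
            pass

    # empirical-Bayes modes and conditional SDs at the optimum
    struct, thetas, omegas, sigma = pmap.unpack(x_opt)
    pred = _make_predictor(pmap, design, struct, thetas)
    eta_hat, q, Amat, _ = _inner_laplace(pred, design, omegas, sigma,
                                         np.zeros((design.n_arms, pmap.n_eta)))
    d = pmap.n_eta
    H_in = Amat.copy()
    H_in[:, np.arange(d), np.arange(d)] += 1.0 / omegas ** 2
    cond_cov = np.linalg.inv(H_in)
    eb = {sid: {"eta": tuple(eta_hat[i]),
                "cond_sd": tuple(np.sqrt(np.diag(cond_cov[i])))}
          for i, sid in enumerate(design.arm_ids)}

    return FitResult(estimates={k: float(nat[k]) for k in pmap.names},
                     se=se, rse_pct=rse, ofv=ofv, eb_effects=eb,
                     converged=converged, n_arms=design.n_arms,
                     endpoint=endpoint, base_hazard=base_hazard,
                     covariate_spec=list(design.effects), obs_scale=obs_scale,
                     x_opt=x_opt, names=list(pmap.names),
                     hessian_finite=hessian_finite)


def evaluate_ofv(corpus: Corpus, endpoint: str, values: dict,
                 base_hazard: str = "lognormal",
                 covariate_spec: Optional[Sequence[CovariateEffect]] = None,
                 obs_scale: str = "logit") -> float:
    """OFV at fixed natural parameter values (no optimization).

    ``values`` uses the same names as FitResult.estimates.
    """
    covariate_spec = list(covariate_spec or [])
    design = _build_design(corpus, endpoint, covariate_spec, obs_scale)
    pmap = _ParamMap(endpoint, base_hazard, design.effects)
    nll, _ = _make_objective(design, pmap)
    return 2.0 * nll(pmap.pack(values))


def select_base_hazard(corpus: Corpus,
                       candidates: Sequence[str] = ("lognormal", "weibull",
                                                    "loglogistic",
                                                    "exponential"),
                       **fit_kwargs) -> pd.DataFrame:
    """Fit each candidate base hazard to the OS data and rank by AIC.

    Ties in AIC are broken in favor of fewer parameters. Non-convergent
    candidates are excluded (logged).
    """
    rows = []
    for hz in candidates:
        try:
            r = fit(corpus, "OS", base_hazard=hz, compute_se=False,
                    **fit_kwargs)
        except Exception as e:  # noqa: BLE001 - candidate exclusion is logged
            logger.warning("candidate %s failed: %s", hz, e)
            continue
        if not r.converged:
            logger.warning("candidate %s did not converge; excluded", hz)
            continue
        rows.append({"base_hazard": hz, "ofv": r.ofv, "n_params": r.n_params,
                     "aic": r.aic})
    if not rows:
        raise RuntimeError("no base-hazard candidate converged")
    df = pd.DataFrame(rows).sort_values(["aic", "n_params"],
                                        kind="mergesort").reset_index(drop=True)
    return df


def covariate_search(corpus: Corpus, endpoint: str,
                     candidates: Sequence[CovariateEffect],
                     **fit_kwargs):
    """Stepwise covariate model building.

    Forward inclusion requires an OFV drop > 3.84 (p < 0.05, df 1); backward
    elimination removes effects whose deletion raises the OFV by < 6.63
    (p < 0.01). Returns (final FitResult, trace DataFrame).
    """
    candidates = list(candidates)
    search_kw = dict(fit_kwargs)
    search_kw["compute_se"] = False
    trace = []
    included: list = []
    current = fit(corpus, endpoint, covariate_spec=included, **search_kw)
    step = 0
    remaining = candidates[:]
    while remaining:
        trials = []
        for c in remaining:
            r = fit(corpus, endpoint, covariate_spec=included + [c],
                    **search_kw)
            trials.append((current.ofv - r.ofv, c, r))
        trials.sort(key=lambda z: -z[0])
        dofv, c, r = trials[0]
        step += 1
        if dofv > FORWARD_DOFV:
            trace.append({"step": step, "phase": "forward", "covariate":
                          c.label, "ofv": r.ofv, "delta_ofv": dofv,
                          "decision": "include"})
            included.append(c)
            current = r
            remaining.remove(c)
        else:
            trace.append({"step": step, "phase": "forward", "covariate":
                          c.label, "ofv": r.ofv, "delta_ofv": dofv,
                          "decision": "stop"})
            break
    # backward elimination
    changed = True
    while changed and included:
        changed = False
        trials = []
        for c in included:
            rest = [e for e in included if e is not c]
            r = fit(corpus, endpoint, covariate_spec=rest, **search_kw)
            trials.append((r.ofv - current.ofv, c, r))
        trials.sort(key=lambda z: z[0])
        dofv, c, r = trials[0]
        step += 1
        if dofv < BACKWARD_DOFV:
            trace.append({"step": step, "phase": "backward", "covariate":
                          c.label, "ofv": r.ofv, "delta_ofv": dofv,
                          "decision": "remove"})
            included = [e for e in included if e is not c]
            current = r
            changed = True
        else:
            trace.append({"step": step, "phase": "backward", "covariate":
                          c.label, "ofv": r.ofv, "delta_ofv": dofv,
                          "decision": "keep"})
    final = fit(corpus, endpoint,
                covariate_spec=[dc_replace(e) for e in included], **fit_kwargs)
    return final, pd.DataFrame(trace, columns=["step", "phase", "covariate",
                                                 "ofv", "delta_ofv",
                                                 "decision"])


def empirical_bayes(fit_result: FitResult, corpus: Corpus) -> pd.DataFrame:
    """Per-study parameter estimates from the random-effect posterior modes.

    Study-level values are param * exp(eta_hat); conditional SEs follow by
    the delta method from the conditional SD of eta. Covariate effects act
    on the hazard (OS) or on parameters not carrying random effects, so the
    returned study-level parameters are already referenced to the typical
    covariate profile.
    """
    if not fit_result.converged:
        raise ValueError("empirical_bayes requires a converged fit")
    rows = []
    pm = _ParamMap(fit_result.endpoint, fit_result.base_hazard,
                   fit_result.covariate_spec)
    for sid, eb in fit_result.eb_effects.items():
        row = {"study_id": sid}
        for k, pname in enumerate(pm.eta_on):
            base = fit_result.estimates[pname]
            val = base * np.exp(eb["eta"][k])
            row[f"eta_{pname}"] = eb["eta"][k]
            row[pname] = val
            row[f"se_{pname}"] = abs(val) * eb["cond_sd"][k]
            row[f"cond_sd_eta_{pname}"] = eb["cond_sd"][k]
        rows.append(row)
    return pd.DataFrame(rows)


def bootstrap(corpus: Corpus, endpoint: str, n_reps: int = 1000,
              seed: int = 0, base_fit: Optional[FitResult] = None,
              **fit_kwargs) -> BootstrapResult:
    """Nonparametric study-level bootstrap of the final model.

    Arms with the endpoint are resampled with replacement; each replicate is
    refit (warm-started at the point estimates). A replicate succeeds if the
    optimizer converges with a finite Hessian-based SE set. Aborts if more
    than half of the replicates fail.
    """
    if base_fit is None:
        base_fit = fit(corpus, endpoint,
                       covariate_spec=fit_kwargs.get("covariate_spec"),
                       **{k: v for k, v in fit_kwargs.items()
                          if k != "covariate_spec"})
    if not base_fit.converged:
        raise ValueError("bootstrap requires a converged base fit")
    arms = list(corpus.subset(endpoint))
    rng = np.random.default_rng(seed)
    records = []
    n_success = 0
    kw = dict(fit_kwargs)
    kw.setdefault("covariate_spec", base_fit.covariate_spec)
    kw.setdefault("base_hazard", base_fit.base_hazard)
    kw.setdefault("obs_scale", base_fit.obs_scale)
    kw["n_starts"] = 1
    for rep in range(n_reps):
        idx = rng.integers(0, len(arms), size=len(arms))
        res_arms = [dc_replace(arms[i], study_id=f"{arms[i].study_id}#{j}")
                    for j, i in enumerate(idx)]
        try:
            r = fit(Corpus(tuple(res_arms)), endpoint, x0=base_fit.x_opt,
                    **kw)
            # NONMEM-style success: minimization converged with a finite
            # Hessian; a failed covariance step (SEs NA) still counts
            ok = r.converged and r.hessian_finite is not False
        except Exception as e:  # noqa: BLE001 - failure counts as non-success
            logger.debug("bootstrap replicate %d failed: %s", rep, e)
            ok = False
        if ok:
            n_success += 1
            records.append(r.estimates)
    if n_success < 0.5 * n_reps:
        raise RuntimeError(f"bootstrap aborted: only {n_success}/{n_reps} "
                           "replicates converged")
    df = pd.DataFrame(records)
    med = {k: float(df[k].median()) for k in df.columns}
    ci = {k: (float(np.percentile(df[k], 2.5)),
              float(np.percentile(df[k], 97.5))) for k in df.columns}
    return BootstrapResult(n_attempted=n_reps, n_success=n_success,
                           median=med, ci95=ci, replicates=df)
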