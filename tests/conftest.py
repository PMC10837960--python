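"""Shared fixtures: synthetic corpora and fitted models (session-scoped,
since NLME fits are the expensive step)."""

import dataclasses

import pytest

from alsmbma.reference import PLACEBO_EMAX_PARAMS, PLACEBO_OS_PARAMS
from alsmbma.synthetic_data import GeneratorConfig, generate
from alsmbma.nlme_fit import fit, os_final_covariates


@pytest.fixture(scope="session")
def default_corpus():
    """A full-size synthetic corpus at the published generating values."""
    return generate(GeneratorConfig(seed=2))


@pytest.fixture(scope="session")
def noiseless_corpus():
    """Observations exactly on the structural curves (no eta, no residual)."""
    osp = dataclasses.replace(PLACEBO_OS_PARAMS, eta_sd_sigm=0.0,
                              eta_sd_mu=0.0, eps_sd=0.0)
    emp = dataclasses.replace(PLACEBO_EMAX_PARAMS, eta_sd_emax=0.0,
                              eta_sd_gamma=0.0, eps_sd=0.0)
    return generate(GeneratorConfig(seed=7, os_params=osp, emax_params=emp))


@pytest.fixture(scope="session")
def alsfrs_fit(default_corpus):
    r = fit(default_corpus, "ALSFRS", n_starts=2, seed=0)
    assert r.converged
    return r


@pytest.fixture(scope="session")
def os_fit(default_corpus):
    r = fit(default_corpus, "OS", covariate_spec=os_final_covariates(),
            n_starts=2, seed=0)
    assert r.converged
    return r
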