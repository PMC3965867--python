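import math

import numpy as np
import pytest
from scipy.stats import norm

import pemjoint as pj
from pemjoint.longitudinal import longitudinal_design_matrix
from pemjoint.recurrence import recurrence_design_row


@pytest.fixture(scope="session")
def paper_params():
    return pj.default_paper_params()


@pytest.fixture(scope="session")
def small_cohort():
    """20 subjects at the default truth — enough structure for identities."""
    return pj.simulate_cohort(pj.GeneratorConfig(n_subjects=20, seed=42))


@pytest.fixture(scope="session")
def medium_cohort():
    """60 subjects — used for fit-level checks that need stable optima."""
    return pj.simulate_cohort(pj.GeneratorConfig(n_subjects=60, seed=7))


def override_params(params, **updates):
    """Return a copy of a ParameterSet with named entries replaced."""
    values = params.to_vector()
    names = params.names()
    for key, val in updates.items():
        values[names.index(key)] = val
    return pj.ParameterSet.from_vector(values, params)


def trapezoid_marginal_loglik(subject, params, npts=20000, span=10.0):
    """Brute-force marginal log-likelihood by trapezoid integration over the
    shared random effect, built directly from the model densities (independent
    of the quadrature engine)."""
    sa = params.random_effect.sigma_alpha
    se = params.longitudinal.sigma_e
    beta = params.longitudinal.beta
    grid = np.linspace(-span * sa, span * sa, npts)

    X = longitudinal_design_matrix(subject)
    y = np.array([o.y for o in subject.observations])
    resid = (y - X @ beta)[:, None] - grid[None, :]
    ll_long = -0.5 * len(y) * math.log(2 * math.pi * se**2) - (resid**2).sum(0) / (2 * se**2)

    z = float(recurrence_design_row(subject.covariates) @ params.recurrence.eta)
    g = params.recurrence.gamma
    base = params.recurrence.baseline
    Hsum = sum(float(base.cumulative(e.w)) for e in subject.episodes)
    Lh = sum(math.log(float(base.hazard(e.w))) for e in subject.episodes if e.delta)
    D = sum(e.delta for e in subject.episodes)
    ll_rec = Lh + D * (z + g * grid) - Hsum * np.exp(z + g * grid)

    logint = ll_long + ll_rec + norm.logpdf(grid, 0.0, sa)
    m = logint.max()
    return m + math.log(np.trapezoid(np.exp(logint - m), grid))
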