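"""Linear mixed submodel for the transformed IgG titer.

Model: for subject ``i`` at visit time ``t_ij`` (months since onset),

    y_ij = x_ij' beta + alpha_i + e_ij,
    alpha_i ~ N(0, sigma_alpha^2),   e_ij ~ N(0, sigma_e^2) iid,

with ``y = ln(1 + titer)`` and design row
``x = (1, age, male, single, lymphocyte, t)``. ``alpha_i`` is the shared
random intercept that also enters the recurrence hazard, which is what links
the two processes.

Marginally over ``alpha`` the within-subject covariance is compound symmetry,
``sigma_alpha^2 J + sigma_e^2 I``; :func:`marginal_loglik_long` evaluates
that closed form and serves as the exact oracle for the quadrature-based
joint likelihood.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core_types import SubjectCovariates, SubjectData, ValidationError

__all__ = [
    "LONG_DESIGN_COLUMNS",
    "LongitudinalParams",
    "RandomEffectParams",
    "longitudinal_design_row",
    "longitudinal_design_matrix",
    "cond_loglik_long",
    "marginal_loglik_long",
]

#: fixed order of the longitudinal fixed-effect coefficients.
LONG_DESIGN_COLUMNS = ("intercept", "age", "male", "single", "lymphocyte", "time")

_LOG_2PI = math.log(2.0 * math.pi)


@dataclass
class LongitudinalParams:
    """Fixed effects ``beta`` (order :data:`LONG_DESIGN_COLUMNS`, per-unit
    effects on ``ln(1 + IgG)``) and residual SD ``sigma_e > 0``."""

    beta: np.ndarray
    sigma_e: float

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        if self.beta.shape != (len(LONG_DESIGN_COLUMNS),):
            raise ValidationError(
                f"beta must have {len(LONG_DESIGN_COLUMNS)} entries {LONG_DESIGN_COLUMNS}, "
                f"got shape {self.beta.shape}"
            )
        if not np.all(np.isfinite(self.beta)):
            raise ValidationError("beta must be finite")
        # sigma_e = 0 is allowed as a degenerate noise-free limit for
        # simulation; the likelihood functions require sigma_e > 0
        if not (math.isfinite(self.sigma_e) and self.sigma_e >= 0):
            raise ValidationError(f"sigma_e must be >= 0, got {self.sigma_e!r}")


@dataclass
class RandomEffectParams:
    """SD of the shared random intercept, ``sigma_alpha >= 0``."""

    sigma_alpha: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.sigma_alpha) and self.sigma_alpha >= 0):
            raise ValidationError(f"sigma_alpha must be >= 0, got {self.sigma_alpha!r}")


def longitudinal_design_row(covariates: SubjectCovariates, t: float) -> np.ndarray:
    """Design row ``(1, age, male, single, lymphocyte, t)`` at visit time ``t``."""
    if not (math.isfinite(t) and t >= 0):
        raise ValidationError(f"visit time must be finite and >= 0, got {t!r}")
    return np.array(
        [1.0, covariates.age, covariates.male, covariates.single, covariates.lymphocyte, t]
    )


def longitudinal_design_matrix(subject: SubjectData) -> np.ndarray:
    """Stack design rows for all of a subject's observations (n_i x 6)."""
    if not subject.observations:
        return np.empty((0, len(LONG_DESIGN_COLUMNS)))
    return np.vstack([longitudinal_design_row(subject.covariates, o.t) for o in subject.observations])


def cond_loglik_long(subject: SubjectData, params: LongitudinalParams, alpha: float) -> float:
    """Log-likelihood of the subject's measurements given the random effect.

    Sum over observations of the ``N(x'beta + alpha, sigma_e^2)`` log density;
    a subject with no observations contributes 0.
    """
    if not subject.observations:
        return 0.0
    if params.sigma_e <= 0:
        raise ValidationError("cond_loglik_long requires sigma_e > 0")
    X = longitudinal_design_matrix(subject)
    y = np.array([o.y for o in subject.observations])
    resid = y - X @ params.beta - alpha
    n = len(y)
    return float(-0.5 * n * (_LOG_2PI + 2.0 * math.log(params.sigma_e))
                 - 0.5 * np.dot(resid, resid) / params.sigma_e**2)


def marginal_loglik_long(
    subject: SubjectData, params: LongitudinalParams, re: RandomEffectParams
) -> float:
    """Closed-form marginal log-likelihood, integrating out ``alpha``.

    The y-vector is multivariate normal with mean ``X beta`` and
    compound-symmetry covariance ``sigma_alpha^2 J + sigma_e^2 I``. Using
    ``Sigma^{-1} = (I - c J) / sigma_e^2`` with
    ``c = sigma_alpha^2 / (sigma_e^2 + n sigma_alpha^2)`` and
    ``log det Sigma = (n-1) log sigma_e^2 + log(sigma_e^2 + n sigma_alpha^2)``,
    only the residual sum, sum of squares and count are needed.
    """
    if not subject.observations:
        return 0.0
    if params.sigma_e <= 0:
        raise ValidationError("marginal_loglik_long requires sigma_e > 0")
    X = longitudinal_design_matrix(subject)
    y = np.array([o.y for o in subject.observations])
    r = y - X @ params.beta
    n = len(y)
    se2 = params.sigma_e**2
    sa2 = re.sigma_alpha**2
    tau = se2 + n * sa2
    quad = (np.dot(r, r) - (sa2 / tau) * np.sum(r) ** 2) / se2
    logdet = (n - 1) * math.log(se2) + math.log(tau)
    return float(-0.5 * (n * _LOG_2PI + logdet + quad))
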