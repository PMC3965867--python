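"""Joint maximum-likelihood estimation over the shared random effect.

Conditional on the subject-level random intercept ``alpha``, the longitudinal
measurements and the recurrent gap times are independent, so each subject's
marginal likelihood is

    L_i = int exp{ ll_long(alpha) + ll_rec(alpha) } phi(alpha; 0, sigma_alpha^2) d alpha,

evaluated here by adaptive Gauss-Hermite quadrature: the integrand's mode and
curvature are located per subject (safeguarded Newton — the log integrand is
strictly concave in ``alpha``) and the standard nodes are recentered and
rescaled there, all on the log scale.

Everything the quadrature needs reduces to per-subject sufficient statistics
(counts, residual sums and sums of squares, event counts, cumulative-hazard
sums), so one likelihood-plus-gradient evaluation is O(rows + subjects x
nodes). Gradients are posterior expectations of the conditional score and are
computed from the same node weights, which keeps full cohort fits fast enough
for simulation studies.

Estimation is by L-BFGS-B on an unconstrained parameterization (SDs and
baseline-hazard parameters log-transformed) from a staged initialization:
closed-form-profile mixed-model fit, then a frailty-free recurrence fit, then
the joint polish. Standard errors come from the observed information
(central-difference Hessian of the analytic gradient), delta-method-mapped to
the reported scale.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize, stats
from scipy.special import logsumexp

from .core_types import Cohort, SubjectData, ValidationError
from .longitudinal import (
    LONG_DESIGN_COLUMNS,
    LongitudinalParams,
    RandomEffectParams,
    longitudinal_design_matrix,
    marginal_loglik_long,
)
from .recurrence import (
    REC_DESIGN_COLUMNS,
    BaselineHazard,
    RecurrenceParams,
    recurrence_design_row,
)

__all__ = [
    "ParameterSet",
    "QuadratureRule",
    "FitResult",
    "JointModel",
    "subject_marginal_loglik",
    "joint_loglik",
    "fit_joint",
    "fit_longitudinal",
    "fit_recurrence_null",
    "standard_errors",
    "wald_ci",
    "hazard_ratio",
    "percent_change_per_unit",
]

_LOG_2PI = math.log(2.0 * math.pi)
_EXP_CAP = 500.0  # cap on log-scale frailty exponents to avoid overflow mid-optimization


def _safe_exp(x):
    return np.exp(np.minimum(x, _EXP_CAP))


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------


@dataclass
class ParameterSet:
    """All joint-model parameters.

    The unconstrained optimization vector is ordered: longitudinal beta
    (:data:`LONG_DESIGN_COLUMNS`), log sigma_e, log sigma_alpha, eta
    (:data:`REC_DESIGN_COLUMNS`), gamma, then log baseline-hazard parameters
    (Weibull: log rate, log shape; piecewise: one log rate per piece).
    """

    longitudinal: LongitudinalParams
    random_effect: RandomEffectParams
    recurrence: RecurrenceParams

    def names(self) -> list[str]:
        base = self.recurrence.baseline
        if base.family == "weibull":
            bnames = ["weibull_rate", "weibull_shape"]
        else:
            bnames = [f"piecewise_rate_{j + 1}" for j in range(len(base.rates))]
        return (
            [f"long_{c}" for c in LONG_DESIGN_COLUMNS]
            + ["sigma_e", "sigma_alpha"]
            + [f"rec_{c}" for c in REC_DESIGN_COLUMNS]
            + ["gamma"]
            + bnames
        )

    def to_vector(self) -> np.ndarray:
        """Natural (reported-scale) parameter vector, in :meth:`names` order."""
        base = self.recurrence.baseline
        bvals = [base.rate, base.shape] if base.family == "weibull" else list(base.rates)
        return np.concatenate(
            [
                self.longitudinal.beta,
                [self.longitudinal.sigma_e, self.random_effect.sigma_alpha],
                self.recurrence.eta,
                [self.recurrence.gamma],
                bvals,
            ]
        )

    @classmethod
    def from_vector(cls, values: np.ndarray, template: "ParameterSet") -> "ParameterSet":
        values = np.asarray(values, dtype=float)
        p = len(LONG_DESIGN_COLUMNS)
        q = len(REC_DESIGN_COLUMNS)
        base = template.recurrence.baseline
        beta = values[:p]
        sigma_e, sigma_alpha = values[p], values[p + 1]
        eta = values[p + 2 : p + 2 + q]
        gamma = values[p + 2 + q]
        bvals = values[p + 3 + q :]
        if base.family == "weibull":
            baseline = BaselineHazard(family="weibull", rate=bvals[0], shape=bvals[1])
        else:
            baseline = BaselineHazard(
                family="piecewise_constant", knots=base.knots.copy(), rates=bvals.copy()
            )
        return cls(
            longitudinal=LongitudinalParams(beta=beta, sigma_e=sigma_e),
            random_effect=RandomEffectParams(sigma_alpha=sigma_alpha),
            recurrence=RecurrenceParams(eta=eta, gamma=gamma, baseline=baseline),
        )


@dataclass
class QuadratureRule:
    """Gauss-Hermite rule (physicists' convention, weight ``exp(-x^2)``).

    With ``adaptive=True`` nodes are recentered at each subject's integrand
    mode and rescaled by its curvature, which keeps low orders accurate; with
    ``adaptive=False`` nodes are centered at 0 and scaled by ``sigma_alpha``.
    """

    order: int
    nodes: np.ndarray
    weights: np.ndarray
    adaptive: bool = True

    @classmethod
    def from_order(cls, order: int = 15, adaptive: bool = True) -> "QuadratureRule":
        if order < 3:
            raise ValidationError(f"quadrature order must be >= 3, got {order}")
        nodes, weights = np.polynomial.hermite.hermgauss(order)
        return cls(order=order, nodes=nodes, weights=weights, adaptive=adaptive)

    def normal_identity_error(self) -> float:
        """|1 - integral of the standard normal density| under this rule."""
        total = math.sqrt(2.0) * np.sum(self.weights * stats.norm.pdf(math.sqrt(2.0) * self.nodes) * np.exp(self.nodes**2))
        return abs(1.0 - float(total))


# ---------------------------------------------------------------------------
# flattened cohort arrays + likelihood engine
# ---------------------------------------------------------------------------


class _CohortArrays:
    """Cohort flattened into contiguous arrays, with optional centering of the
    continuous longitudinal covariates (age, lymphocyte, time) for optimizer
    conditioning. Centering is a linear reparameterization of the intercept
    and is inverted exactly before reporting."""

    CENTER_COLS = (1, 4, 5)  # age, lymphocyte, time

    def __init__(self, cohort: Cohort, center: bool = True):
        X_blocks, y_blocks, obs_idx = [], [], []
        Z_rows = []
        w_list, d_list, epi_idx = [], [], []
        for i, s in enumerate(cohort.subjects):
            Xi = longitudinal_design_matrix(s)
            X_blocks.append(Xi)
            y_blocks.append(np.array([o.y for o in s.observations], dtype=float))
            obs_idx.append(np.full(len(s.observations), i))
            Z_rows.append(recurrence_design_row(s.covariates))
            for e in s.episodes:
                w_list.append(e.w)
                d_list.append(float(e.delta))
                epi_idx.append(i)
        self.n = len(cohort.subjects)
        self.X = np.vstack(X_blocks) if X_blocks else np.empty((0, len(LONG_DESIGN_COLUMNS)))
        self.y = np.concatenate(y_blocks) if y_blocks else np.empty(0)
        self.obs_idx = np.concatenate(obs_idx).astype(np.intp) if obs_idx else np.empty(0, np.intp)
        self.Z = np.vstack(Z_rows) if Z_rows else np.empty((0, len(REC_DESIGN_COLUMNS)))
        self.w = np.asarray(w_list, dtype=float)
        self.delta = np.asarray(d_list, dtype=float)
        self.epi_idx = np.asarray(epi_idx, dtype=np.intp)
        self.logw = np.log(self.w) if self.w.size else self.w

        self.offsets = np.zeros(self.X.shape[1])
        if center and len(self.y):
            for c in self.CENTER_COLS:
                self.offsets[c] = self.X[:, c].mean()
        self.Xc = self.X - self.offsets

        self.n_obs_i = np.bincount(self.obs_idx, minlength=self.n).astype(float)
        self.Sx = np.zeros((self.n, self.Xc.shape[1]))
        for c in range(self.Xc.shape[1]):
            self.Sx[:, c] = np.bincount(self.obs_idx, weights=self.Xc[:, c], minlength=self.n)
        self.D = np.bincount(self.epi_idx, weights=self.delta, minlength=self.n)
        self.Sdlogw = np.bincount(self.epi_idx, weights=self.delta * self.logw, minlength=self.n) if self.w.size else np.zeros(self.n)
        self.n_events = float(self.D.sum())
        self.total_gap = float(self.w.sum())

    # -- parameter plumbing -------------------------------------------------

    def theta_from_params(self, params: ParameterSet) -> np.ndarray:
        """Map a reported-scale ParameterSet to the internal unconstrained vector."""
        v = params.to_vector()
        p = len(LONG_DESIGN_COLUMNS)
        q = len(REC_DESIGN_COLUMNS)
        theta = v.copy()
        theta[0] = v[0] + float(self.offsets @ v[:p])  # intercept absorbs centering
        theta[p] = math.log(v[p])
        theta[p + 1] = math.log(max(v[p + 1], 1e-12))
        theta[p + 2 + q + 1 :] = np.log(v[p + 2 + q + 1 :])
        return theta

    def params_from_theta(self, theta: np.ndarray, template: ParameterSet) -> ParameterSet:
        return ParameterSet.from_vector(self.reported_from_theta(theta), template)

    def reported_from_theta(self, theta: np.ndarray) -> np.ndarray:
        p = len(LONG_DESIGN_COLUMNS)
        q = len(REC_DESIGN_COLUMNS)
        v = np.array(theta, dtype=float)
        v[0] = theta[0] - float(self.offsets @ np.concatenate([[0.0], theta[1:p]]))
        v[p] = math.exp(theta[p])
        v[p + 1] = math.exp(theta[p + 1])
        v[p + 2 + q + 1 :] = np.exp(theta[p + 2 + q + 1 :])
        return v

    def report_jacobian(self, theta: np.ndarray) -> np.ndarray:
        """Jacobian of reported parameters w.r.t. the internal vector."""
        p = len(LONG_DESIGN_COLUMNS)
        q = len(REC_DESIGN_COLUMNS)
        k = len(theta)
        J = np.eye(k)
        for c in range(1, p):
            J[0, c] = -self.offsets[c]
        J[p, p] = math.exp(theta[p])
        J[p + 1, p + 1] = math.exp(theta[p + 1])
        for j in range(p + 2 + q + 1, k):
            J[j, j] = math.exp(theta[j])
        return J

    # -- baseline-hazard pieces ----------------------------------------------

    def _baseline_terms(self, theta, baseline_template: BaselineHazard):
        """Per-episode log h0(w) and H0(w) plus gradient helpers."""
        p = len(LONG_DESIGN_COLUMNS)
        q = len(REC_DESIGN_COLUMNS)
        bpar = theta[p + 2 + q + 1 :]
        if baseline_template.family == "weibull":
            loglam, logp = bpar
            shape = math.exp(logp)
            logh0 = loglam + logp + (shape - 1.0) * self.logw
            H0 = np.exp(loglam + shape * self.logw)
            return logh0, H0, {"shape": shape}
        rates = np.exp(bpar)
        knots = baseline_template.knots
        if not hasattr(self, "_pw_overlap"):
            upper = np.append(knots[1:], np.inf)
            self._pw_overlap = np.clip(
                np.clip(self.w[:, None], None, upper[None, :]) - knots[None, :], 0.0, None
            )
            self._pw_piece = (np.searchsorted(knots, self.w, side="right") - 1).astype(np.intp)
        logh0 = np.log(rates)[self._pw_piece]
        H0 = self._pw_overlap @ rates
        return logh0, H0, {"rates": rates}

    # -- the marginal log-likelihood and its gradient -------------------------

    def loglik_parts(self, theta, rule: QuadratureRule, baseline_template: BaselineHazard, want_grad: bool):
        """Per-subject marginal log-likelihoods (and the total gradient)."""
        p = len(LONG_DESIGN_COLUMNS)
        q = len(REC_DESIGN_COLUMNS)
        beta = theta[:p]
        log_se, log_sa = theta[p], theta[p + 1]
        eta = theta[p + 2 : p + 2 + q]
        gamma = theta[p + 2 + q]
        se2 = math.exp(2.0 * log_se)
        sa2 = math.exp(2.0 * log_sa)

        r = self.y - self.Xc @ beta
        Sy = np.bincount(self.obs_idx, weights=r, minlength=self.n)
        SS = np.bincount(self.obs_idx, weights=r * r, minlength=self.n)
        ni = self.n_obs_i

        zeta = self.Z @ eta
        logh0, H0, bextra = self._baseline_terms(theta, baseline_template)
        Hsum = np.bincount(self.epi_idx, weights=H0, minlength=self.n)
        Lh = np.bincount(self.epi_idx, weights=self.delta * logh0, minlength=self.n)
        A = _safe_exp(zeta) * Hsum  # scaled cumulative hazard, exp(zeta) * sum H0

        const = (
            -0.5 * ni * (_LOG_2PI + 2.0 * log_se)
            + Lh
            + self.D * zeta
            - 0.5 * (_LOG_2PI + 2.0 * log_sa)
        )

        def g_and_derivs(a):
            ea = _safe_exp(gamma * a)
            g = (
                const
                - 0.5 * (SS - 2.0 * Sy * a + ni * a * a) / se2
                + self.D * gamma * a
                - A * ea
                - 0.5 * a * a / sa2
            )
            g1 = (Sy - ni * a) / se2 + gamma * self.D - gamma * A * ea - a / sa2
            g2 = -ni / se2 - gamma * gamma * A * ea - 1.0 / sa2
            return g, g1, g2

        if rule.adaptive:
            # safeguarded Newton on the strictly concave log integrand
            a = np.zeros(self.n)
            for _ in range(100):
                _, g1, g2 = g_and_derivs(a)
                step = np.clip(-g1 / g2, -1.0, 1.0)
                a = a + step
                if np.max(np.abs(step)) < 1e-11:
                    break
            mode = a
            _, _, g2 = g_and_derivs(mode)
            shat = 1.0 / np.sqrt(-g2)
            Anodes = mode[:, None] + math.sqrt(2.0) * shat[:, None] * rule.nodes[None, :]
            gq = (
                np.log(rule.weights)[None, :]
                + rule.nodes[None, :] ** 2
                + g_and_derivs_matrix(Anodes, const, SS, Sy, ni, se2, self.D, gamma, A, sa2)
            )
            lse = logsumexp(gq, axis=1)
            ll = 0.5 * math.log(2.0) + np.log(shat) + lse
        else:
            sa = math.exp(log_sa)
            Anodes = np.broadcast_to(math.sqrt(2.0) * sa * rule.nodes[None, :], (self.n, rule.order)).copy()
            gq = (
                np.log(rule.weights)[None, :]
                + g_and_derivs_matrix(Anodes, const, SS, Sy, ni, se2, self.D, gamma, A, sa2)
                + 0.5 * (Anodes / sa) ** 2  # cancel the prior term folded into g
                + 0.5 * (_LOG_2PI + 2.0 * log_sa)  # and its normalizing constant
            )
            ll = logsumexp(gq, axis=1) - 0.5 * math.log(math.pi)

        if not want_grad:
            return ll, None

        W = np.exp(gq - logsumexp(gq, axis=1)[:, None])
        Ea = np.sum(W * Anodes, axis=1)
        Ea2 = np.sum(W * Anodes**2, axis=1)
        eg = _safe_exp(gamma * Anodes)
        Eg = np.sum(W * eg, axis=1)
        Eag = np.sum(W * Anodes * eg, axis=1)

        grad = np.zeros_like(theta)
        Xtr = self.Xc.T @ r
        grad[:p] = (Xtr - self.Sx.T @ Ea) / se2
        grad[p] = float(np.sum(-ni + (SS - 2.0 * Sy * Ea + ni * Ea2) / se2))
        grad[p + 1] = float(np.sum(-1.0 + Ea2 / sa2))
        score_rec = self.D - A * Eg  # per-subject d/d(zeta)
        grad[p + 2 : p + 2 + q] = self.Z.T @ score_rec
        grad[p + 2 + q] = float(np.sum(self.D * Ea - A * Eag))
        if baseline_template.family == "weibull":
            shape = bextra["shape"]
            grad[p + 3 + q] = float(np.sum(score_rec))
            GH = np.bincount(self.epi_idx, weights=H0 * self.logw, minlength=self.n)
            grad[p + 4 + q] = float(
                np.sum(self.D + shape * self.Sdlogw - _safe_exp(zeta) * shape * GH * Eg)
            )
        else:
            rates = bextra["rates"]
            ez_Eg = _safe_exp(zeta) * Eg
            for j in range(len(rates)):
                Nev_j = np.bincount(
                    self.epi_idx, weights=self.delta * (self._pw_piece == j), minlength=self.n
                )
                O_j = np.bincount(self.epi_idx, weights=self._pw_overlap[:, j], minlength=self.n)
                grad[p + 3 + q + j] = float(np.sum(Nev_j - rates[j] * O_j * ez_Eg))
        return ll, grad


def g_and_derivs_matrix(a, const, SS, Sy, ni, se2, D, gamma, A, sa2):
    """Vectorized log integrand over a (subjects x nodes) matrix of alphas."""
    ea = _safe_exp(gamma * a)
    return (
        const[:, None]
        - 0.5 * (SS[:, None] - 2.0 * Sy[:, None] * a + ni[:, None] * a * a) / se2
        + D[:, None] * gamma * a
        - A[:, None] * ea
        - 0.5 * a * a / sa2
    )


# ---------------------------------------------------------------------------
# public likelihood entry points
# ---------------------------------------------------------------------------


def _sum_sorted(values: np.ndarray) -> float:
    """Permutation-invariant compensated sum of per-subject contributions."""
    return math.fsum(np.sort(np.asarray(values, dtype=float)))


def subject_marginal_loglik(
    subject: SubjectData, params: ParameterSet, rule: QuadratureRule | None = None
) -> float:
    """Marginal log-likelihood of one subject, integrating out ``alpha``."""
    from .recurrence import cond_loglik_rec
    from .longitudinal import cond_loglik_long

    if rule is None:
        rule = QuadratureRule.from_order()
    if params.random_effect.sigma_alpha == 0.0:
        return cond_loglik_long(subject, params.longitudinal, 0.0) + cond_loglik_rec(
            subject, params.recurrence, 0.0
        )
    arrays = _CohortArrays(Cohort(subjects=[subject]), center=False)
    theta = arrays.theta_from_params(params)
    ll, _ = arrays.loglik_parts(theta, rule, params.recurrence.baseline, want_grad=False)
    if not np.all(np.isfinite(ll)):
        raise FloatingPointError(
            f"non-finite marginal likelihood for subject {subject.subject_id!r}"
        )
    return float(ll[0])


def joint_loglik(cohort: Cohort, params: ParameterSet, rule: QuadratureRule | None = None) -> float:
    """Cohort log-likelihood: sum of subject marginals (order-invariant sum)."""
    if rule is None:
        rule = QuadratureRule.from_order()
    if params.random_effect.sigma_alpha == 0.0:
        return _sum_sorted([subject_marginal_loglik(s, params, rule) for s in cohort.subjects])
    arrays = _CohortArrays(cohort, center=False)
    theta = arrays.theta_from_params(params)
    ll, _ = arrays.loglik_parts(theta, rule, params.recurrence.baseline, want_grad=False)
    bad = ~np.isfinite(ll)
    if np.any(bad):
        ids = [cohort.subjects[i].subject_id for i in np.nonzero(bad)[0]]
        raise FloatingPointError(f"non-finite marginal likelihood for subjects {ids!r}")
    return _sum_sorted(ll)


# ---------------------------------------------------------------------------
# separate-model fits (initialization + oracles)
# ---------------------------------------------------------------------------


def fit_longitudinal(cohort: Cohort) -> tuple[LongitudinalParams, RandomEffectParams, float]:
    """ML fit of the random-intercept mixed model alone.

    beta is profiled out in closed form (GLS under the compound-symmetry
    covariance) and the two variance parameters are optimized numerically.
    """
    arrays = _CohortArrays(cohort, center=True)
    X, y, idx, n = arrays.Xc, arrays.y, arrays.obs_idx, arrays.n
    ni = arrays.n_obs_i
    XtX = X.T @ X
    Xty = X.T @ y
    Sx = arrays.Sx
    Syy = np.bincount(idx, weights=y, minlength=n)

    def profile_negll(logs):
        se2 = math.exp(2.0 * logs[0])
        sa2 = math.exp(2.0 * logs[1])
        c = sa2 / (se2 + ni * sa2)
        Amat = XtX - (Sx * c[:, None]).T @ Sx
        bvec = Xty - Sx.T @ (c * Syy)
        beta = np.linalg.solve(Amat, bvec)
        r = y - X @ beta
        Sr = np.bincount(idx, weights=r, minlength=n)
        SS = np.bincount(idx, weights=r * r, minlength=n)
        tau = se2 + ni * sa2
        quad = (SS - (sa2 / tau) * Sr**2) / se2
        logdet = (ni - 1.0) * 2.0 * logs[0] * 1.0 + np.log(tau)
        ll = -0.5 * float(np.sum(ni * _LOG_2PI + logdet + quad))
        return -ll, beta

    # moment start: pooled OLS residual decomposition
    beta0 = np.linalg.lstsq(X, y, rcond=None)[0]
    r0 = y - X @ beta0
    within = float(np.mean((r0 - (np.bincount(idx, weights=r0, minlength=n) / ni)[idx]) ** 2))
    means = np.bincount(idx, weights=r0, minlength=n) / ni
    between = max(float(np.var(means)) - within / float(np.mean(ni)), 1e-4)
    x0 = np.array([0.5 * math.log(max(within, 1e-6)), 0.5 * math.log(between)])
    res = optimize.minimize(lambda v: profile_negll(v)[0], x0, method="Nelder-Mead",
                            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 2000})
    negll, beta = profile_negll(res.x)
    sigma_e, sigma_alpha = math.exp(res.x[0]), math.exp(res.x[1])
    # undo centering for the reported intercept
    beta_rep = beta.copy()
    beta_rep[0] = beta[0] - float(arrays.offsets @ np.concatenate([[0.0], beta[1:]]))
    return (
        LongitudinalParams(beta=beta_rep, sigma_e=sigma_e),
        RandomEffectParams(sigma_alpha=sigma_alpha),
        -negll,
    )


def fit_recurrence_null(
    cohort: Cohort, baseline: str = "weibull", knots: Sequence[float] | None = None
) -> tuple[RecurrenceParams, float]:
    """ML fit of the frailty-free (gamma = 0) recurrence submodel."""
    arrays = _CohortArrays(cohort, center=False)
    Z_epi = arrays.Z[arrays.epi_idx]
    w, delta, logw = arrays.w, arrays.delta, arrays.logw
    if baseline == "weibull":
        template = BaselineHazard(family="weibull", rate=1.0, shape=1.0)
        nb = 2
    else:
        kn = np.asarray(knots, dtype=float)
        template = BaselineHazard(family="piecewise_constant", knots=kn, rates=np.ones(len(kn)))
        upper = np.append(kn[1:], np.inf)
        overlap = np.clip(np.clip(w[:, None], None, upper[None, :]) - kn[None, :], 0.0, None)
        piece = (np.searchsorted(kn, w, side="right") - 1).astype(np.intp)
        nb = len(kn)
    q = Z_epi.shape[1]

    def negll_grad(par):
        eta, bpar = par[:q], par[q:]
        zeta = Z_epi @ eta
        if baseline == "weibull":
            loglam, logp = bpar
            shape = math.exp(logp)
            logh0 = loglam + logp + (shape - 1.0) * logw
            H0 = np.exp(np.minimum(loglam + shape * logw, _EXP_CAP))
        else:
            rates = np.exp(bpar)
            logh0 = np.log(rates)[piece]
            H0 = overlap @ rates
        He = H0 * _safe_exp(zeta)
        ll = float(np.sum(delta * (logh0 + zeta) - He))
        score = delta - He
        grad = np.zeros_like(par)
        grad[:q] = Z_epi.T @ score
        if baseline == "weibull":
            grad[q] = float(np.sum(score))
            grad[q + 1] = float(np.sum(delta * (1.0 + shape * logw) - He * shape * logw))
        else:
            for j in range(nb):
                grad[q + j] = float(np.sum(delta * (piece == j) - rates[j] * overlap[:, j] * _safe_exp(zeta)))
        return -ll, -grad

    lam0 = max(arrays.n_events, 1.0) / max(arrays.total_gap, 1e-6)
    x0 = np.concatenate([np.zeros(q), [math.log(lam0)] * (nb - 1 if baseline != "weibull" else 1),
                         [0.0] if baseline == "weibull" else [math.log(lam0)]])
    x0 = x0[: q + nb]
    res = optimize.minimize(negll_grad, x0, jac=True, method="L-BFGS-B",
                            options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-8})
    eta = res.x[:q]
    if baseline == "weibull":
        fitted = BaselineHazard(family="weibull", rate=math.exp(res.x[q]), shape=math.exp(res.x[q + 1]))
    else:
        fitted = BaselineHazard(family="piecewise_constant", knots=template.knots, rates=np.exp(res.x[q:]))
    return RecurrenceParams(eta=eta, gamma=0.0, baseline=fitted), -float(res.fun)


# ---------------------------------------------------------------------------
# fit result + fitter
# ---------------------------------------------------------------------------


@dataclass
class FitResult:
    """Joint-model fit: reported-scale estimates, Wald inference, diagnostics."""

    param_names: list[str]
    estimates: ParameterSet
    values: np.ndarray
    se: np.ndarray | None
    vcov: np.ndarray | None
    loglik: float
    converged: bool
    n_subjects: int
    n_obs: int
    n_episodes: int
    diagnostics: dict = field(default_factory=dict)

    def se_dict(self) -> dict:
        if self.se is None:
            return {}
        return dict(zip(self.param_names, self.se))

    def summary_frame(self, level: float = 0.95):
        """Publication-style table: estimate, SE, Wald p, CI, and the natural
        transform (hazard ratio for recurrence coefficients, %/month for the
        longitudinal time trend)."""
        import pandas as pd

        rows = []
        for j, name in enumerate(self.param_names):
            est = self.values[j]
            se = float(self.se[j]) if self.se is not None and np.isfinite(self.se[j]) else np.nan
            if np.isfinite(se) and se > 0:
                lo, hi = wald_ci(est, se, level)
                pval = 2.0 * stats.norm.sf(abs(est) / se)
            else:
                lo = hi = pval = np.nan
            if name.startswith("rec_") or name == "gamma":
                transformed, tname = hazard_ratio(est), "HR"
            elif name == "long_time":
                transformed, tname = percent_change_per_unit(est), "%/month"
            else:
                transformed, tname = np.nan, ""
            rows.append(
                {"parameter": name, "estimate": est, "se": se, "p_value": pval,
                 "ci_lower": lo, "ci_upper": hi, "transformed": transformed, "transform": tname}
            )
        return pd.DataFrame(rows)

    def table2_text(self, level: float = 0.95) -> str:
        """Fixed-order text table: longitudinal block, recurrent block, gamma."""
        df = self.summary_frame(level)
        labels = {
            "long_age": "Age", "long_male": "Male", "long_single": "Single",
            "long_lymphocyte": "Lymphocyte", "long_time": "Time",
            "rec_age_std": "Age (per SD)", "rec_male": "Male", "rec_single": "Single",
            "rec_skin_phenotype": "Phenotype (skin vs mucosal)", "gamma": "Gamma",
        }
        lines = [f"{'Covariate':<30}{'Estimate':>10}{'SE':>9}{'P':>8}{'Lower':>9}{'Upper':>9}{'Transf':>9}"]

        def block(title, names):
            lines.append(title)
            for nm in names:
                row = df[df.parameter == nm].iloc[0]
                tr = f"{row.transformed:9.3f}" if np.isfinite(row.transformed) else " " * 9
                lines.append(
                    f"  {labels.get(nm, nm):<28}{row.estimate:10.3f}{row.se:9.3f}"
                    f"{row.p_value:8.3f}{row.ci_lower:9.3f}{row.ci_upper:9.3f}{tr}"
                )

        block("Longitudinal measures of IgG",
              ["long_age", "long_male", "long_single", "long_lymphocyte", "long_time"])
        block("Recurrent pemphigus event",
              ["rec_age_std", "rec_male", "rec_single", "rec_skin_phenotype"])
        block("Association", ["gamma"])
        return "\n".join(lines)

    def to_json(self) -> str:
        payload = {
            "param_names": self.param_names,
            "values": self.values.tolist(),
            "se": None if self.se is None else np.asarray(self.se).tolist(),
            "vcov": None if self.vcov is None else np.asarray(self.vcov).tolist(),
            "loglik": self.loglik,
            "converged": self.converged,
            "n_subjects": self.n_subjects,
            "n_obs": self.n_obs,
            "n_episodes": self.n_episodes,
            "baseline_family": self.estimates.recurrence.baseline.family,
            "baseline_knots": None
            if self.estimates.recurrence.baseline.knots is None
            else np.asarray(self.estimates.recurrence.baseline.knots).tolist(),
            "diagnostics": {k: v for k, v in self.diagnostics.items() if _json_safe(v)},
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "FitResult":
        d = json.loads(text)
        if d["baseline_family"] == "weibull":
            base = BaselineHazard(family="weibull", rate=1.0, shape=1.0)
        else:
            kn = np.asarray(d["baseline_knots"])
            base = BaselineHazard(family="piecewise_constant", knots=kn, rates=np.ones(len(kn)))
        template = ParameterSet(
            longitudinal=LongitudinalParams(beta=np.zeros(len(LONG_DESIGN_COLUMNS)), sigma_e=1.0),
            random_effect=RandomEffectParams(sigma_alpha=1.0),
            recurrence=RecurrenceParams(eta=np.zeros(len(REC_DESIGN_COLUMNS)), gamma=0.0, baseline=base),
        )
        values = np.asarray(d["values"])
        return cls(
            param_names=d["param_names"],
            estimates=ParameterSet.from_vector(values, template),
            values=values,
            se=None if d["se"] is None else np.asarray(d["se"]),
            vcov=None if d["vcov"] is None else np.asarray(d["vcov"]),
            loglik=d["loglik"],
            converged=d["converged"],
            n_subjects=d["n_subjects"],
            n_obs=d["n_obs"],
            n_episodes=d["n_episodes"],
            diagnostics=d.get("diagnostics", {}),
        )


def _json_safe(v) -> bool:
    try:
        json.dumps(v)
        return True
    except TypeError:
        return False


class JointModel:
    """Shared random-effects joint model fitter.

    Hyperparameters live in the constructor, :meth:`fit` consumes a
    :class:`~pemjoint.core_types.Cohort` and returns ``self``, fitted
    quantities carry trailing underscores (``params_``, ``se_``, ``vcov_``,
    ``loglik_``, ``converged_``, ``result_``).

    Parameters
    ----------
    baseline : {"weibull", "piecewise_constant"}
        Baseline-hazard family for the gap-time submodel.
    knots : sequence of float, optional
        Piece boundaries (starting at 0, months) for the piecewise family.
    quad_order : int
        Gauss-Hermite order; adaptive recentering keeps modest orders accurate.
    adaptive : bool
        Recenter/rescale nodes at each subject's integrand mode.
    center : bool
        Center continuous longitudinal covariates internally (reported
        estimates are always mapped back to the raw scale).
    gtol, ftol, max_iter
        Optimizer tolerances (projected-gradient max-norm, relative loglik
        change) and iteration cap.
    compute_se : bool
        Compute the observed-information covariance after fitting.
    fixed : mapping, optional
        Parameter name -> value held fixed during optimization (reported
        scale), e.g. ``{"gamma": 0.0}`` for the no-association null model.
    """

    def __init__(self, baseline: str = "weibull", knots: Sequence[float] | None = None,
                 quad_order: int = 15, adaptive: bool = True, center: bool = True,
                 gtol: float = 1e-5, ftol: float = 1e-12, max_iter: int = 1000,
                 compute_se: bool = True, fixed: Mapping[str, float] | None = None):
        self.baseline = baseline
        self.knots = knots
        self.quad_order = quad_order
        self.adaptive = adaptive
        self.center = center
        self.gtol = gtol
        self.ftol = ftol
        self.max_iter = max_iter
        self.compute_se = compute_se
        self.fixed = fixed

    # sklearn-style parameter plumbing
    _PARAM_KEYS = ("baseline", "knots", "quad_order", "adaptive", "center",
                   "gtol", "ftol", "max_iter", "compute_se", "fixed")

    def get_params(self, deep: bool = True) -> dict:
        return {k: getattr(self, k) for k in self._PARAM_KEYS}

    def set_params(self, **kwargs) -> "JointModel":
        for k, v in kwargs.items():
            if k not in self._PARAM_KEYS:
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    # -- fitting -----------------------------------------------------------

    def _template(self) -> ParameterSet:
        if self.baseline == "weibull":
            base = BaselineHazard(family="weibull", rate=0.1, shape=1.0)
        else:
            kn = np.asarray(self.knots, dtype=float)
            base = BaselineHazard(family="piecewise_constant", knots=kn, rates=np.full(len(kn), 0.1))
        return ParameterSet(
            longitudinal=LongitudinalParams(beta=np.zeros(len(LONG_DESIGN_COLUMNS)), sigma_e=1.0),
            random_effect=RandomEffectParams(sigma_alpha=1.0),
            recurrence=RecurrenceParams(eta=np.zeros(len(REC_DESIGN_COLUMNS)), gamma=0.0, baseline=base),
        )

    def fit(self, cohort: Cohort, init: ParameterSet | None = None) -> "JointModel":
        if len(cohort.subjects) < 2:
            raise ValidationError("joint fit requires at least 2 subjects")
        if cohort.n_events < 1:
            raise ValidationError("joint fit requires at least one observed recurrence")
        template = self._template()
        rule = QuadratureRule.from_order(self.quad_order, adaptive=self.adaptive)
        arrays = _CohortArrays(cohort, center=self.center)

        if init is None:
            long_params, re_params, _ = fit_longitudinal(cohort)
            rec_params, _ = fit_recurrence_null(cohort, baseline=self.baseline, knots=self.knots)
            init = ParameterSet(
                longitudinal=long_params,
                random_effect=RandomEffectParams(sigma_alpha=max(re_params.sigma_alpha, 1e-3)),
                recurrence=rec_params,
            )
        theta0 = arrays.theta_from_params(init)

        names = template.names()
        fixed = dict(self.fixed or {})
        unknown = set(fixed) - set(names)
        if unknown:
            raise ValidationError(f"unknown fixed parameters {sorted(unknown)!r}")
        fixed_idx = np.array([names.index(k) for k in fixed], dtype=np.intp)
        if len(fixed_idx):
            vals = arrays.reported_from_theta(theta0)
            for k, v in fixed.items():
                vals[names.index(k)] = v
            theta0 = arrays.theta_from_params(ParameterSet.from_vector(vals, template))
        free_mask = np.ones(len(theta0), dtype=bool)
        free_mask[fixed_idx] = False

        theta_full = theta0.copy()

        def negll_grad(free):
            theta_full[free_mask] = free
            ll, grad = arrays.loglik_parts(theta_full, rule, template.recurrence.baseline, want_grad=True)
            total = _sum_sorted(ll)
            if not math.isfinite(total):
                return 1e12, np.zeros(int(free_mask.sum()))
            return -total, -grad[free_mask]

        res = optimize.minimize(
            negll_grad, theta0[free_mask], jac=True, method="L-BFGS-B",
            options={"maxiter": self.max_iter, "ftol": self.ftol, "gtol": self.gtol},
        )
        theta_full[free_mask] = res.x
        ll_final, grad_final = arrays.loglik_parts(theta_full, rule, template.recurrence.baseline, True)
        loglik = _sum_sorted(ll_final)
        gmax = float(np.max(np.abs(grad_final[free_mask]))) if free_mask.any() else 0.0
        converged = bool(res.success) or gmax < max(self.gtol * 100.0, 1e-3)

        values = arrays.reported_from_theta(theta_full)
        estimates = ParameterSet.from_vector(values, template)

        se = vcov_rep = None
        diag = {"optimizer_message": str(res.message), "n_iter": int(res.nit),
                "grad_max_norm": gmax, "fixed": sorted(fixed)}
        if self.compute_se:
            se, vcov_rep, hess_ok = _observed_information(
                arrays, theta_full, rule, template.recurrence.baseline, free_mask
            )
            diag["hessian_positive_definite"] = hess_ok

        self.result_ = FitResult(
            param_names=names, estimates=estimates, values=values, se=se, vcov=vcov_rep,
            loglik=float(loglik), converged=converged, n_subjects=len(cohort.subjects),
            n_obs=cohort.n_obs, n_episodes=cohort.n_episodes, diagnostics=diag,
        )
        self.params_ = estimates
        self.se_ = se
        self.vcov_ = vcov_rep
        self.loglik_ = float(loglik)
        self.converged_ = converged
        self._arrays = arrays
        self._theta = theta_full
        self._rule = rule
        self._free_mask = free_mask
        return self


def _observed_information(arrays, theta, rule, baseline_template, free_mask, step_scale=1e-4):
    """Observed-information vcov: central-difference Hessian of the analytic
    gradient, inverted on the free parameters and delta-method-mapped to the
    reported scale. Fixed parameters get NaN standard errors."""
    idx = np.nonzero(free_mask)[0]
    k = len(idx)
    H = np.zeros((k, k))
    for a, j in enumerate(idx):
        h = step_scale * (1.0 + abs(theta[j]))
        tp, tm = theta.copy(), theta.copy()
        tp[j] += h
        tm[j] -= h
        _, gp = arrays.loglik_parts(tp, rule, baseline_template, True)
        _, gm = arrays.loglik_parts(tm, rule, baseline_template, True)
        H[a] = (gp[idx] - gm[idx]) / (2.0 * h)
    H = 0.5 * (H + H.T)
    neg_H = -H
    try:
        np.linalg.cholesky(neg_H)
        hess_ok = True
        vcov_free = np.linalg.inv(neg_H)
    except np.linalg.LinAlgError:
        hess_ok = False
        vcov_free = np.full((k, k), np.nan)
    n_par = len(theta)
    vcov_int = np.zeros((n_par, n_par))
    vcov_int[np.ix_(idx, idx)] = vcov_free
    J = arrays.report_jacobian(theta)
    vcov_rep = J @ vcov_int @ J.T
    se = np.sqrt(np.clip(np.diag(vcov_rep), 0.0, None))
    se[~free_mask] = np.nan
    if not hess_ok:
        se[free_mask] = np.nan
    return se, vcov_rep, hess_ok


def fit_joint(cohort: Cohort, init: ParameterSet | None = None, **config) -> FitResult:
    """Functional wrapper around :class:`JointModel`. See its docstring."""
    model = JointModel(**config)
    model.fit(cohort, init=init)
    return model.result_


def standard_errors(
    cohort: Cohort,
    params: ParameterSet,
    rule: QuadratureRule | None = None,
    fixed: Mapping[str, float] | None = None,
    center: bool = True,
    step_scale: float = 1e-4,
):
    """Observed-information SEs and covariance at given (fitted) parameters."""
    if rule is None:
        rule = QuadratureRule.from_order()
    arrays = _CohortArrays(cohort, center=center)
    theta = arrays.theta_from_params(params)
    names = params.names()
    free_mask = np.ones(len(theta), dtype=bool)
    for k in fixed or {}:
        free_mask[names.index(k)] = False
    se, vcov, ok = _observed_information(
        arrays, theta, rule, params.recurrence.baseline, free_mask, step_scale=step_scale
    )
    return se, vcov, ok


# ---------------------------------------------------------------------------
# reporting transforms
# ---------------------------------------------------------------------------


def wald_ci(estimate: float, se: float, level: float = 0.95) -> tuple[float, float]:
    """Symmetric Wald interval ``estimate +/- z * se`` on the coefficient scale."""
    if not (se > 0 and math.isfinite(se)):
        raise ValidationError(f"se must be > 0, got {se!r}")
    if not (0.0 < level < 1.0):
        raise ValidationError(f"level must be in (0, 1), got {level!r}")
    z = stats.norm.ppf(0.5 * (1.0 + level))
    return estimate - z * se, estimate + z * se


def hazard_ratio(coef: float) -> float:
    """``exp(coef)``: multiplicative effect on the recurrence hazard."""
    return math.exp(coef)


def percent_change_per_unit(coef: float) -> float:
    """``100 * (exp(coef) - 1)``: per-unit multiplicative change, in percent,
    of ``1 + IgG`` implied by a log-scale trend coefficient."""
    return 100.0 * math.expm1(coef)
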