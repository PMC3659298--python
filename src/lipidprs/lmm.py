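"""Random-intercept linear mixed models via profiled likelihood.

The marginal model for the stacked visit vector is

    y = X b + Z u + e,   u_s ~ N(0, s2_u),   e ~ N(0, s2_e I),

with one random intercept per subject, so the marginal covariance
V = s2_u Z Z' + s2_e I is block diagonal by subject with blocks
s2_e (I + g J), g = s2_u / s2_e.  Both the generalized-least-squares
fixed effects and the (restricted) log-likelihood are available in closed
form given g, using the rank-one Woodbury identity per block:

    (I + g J)^-1 = I - g/(1 + g k) J,     log|I + g J| = log(1 + g k)

for a block of k visits.  Fitting therefore reduces to a bounded 1-D
optimization over log g; cost is linear in the number of observations.
The dense K x K construction of V never happens outside test oracles.

Predictions for unseen subjects use the fixed effects only (the random
intercept of a subject never observed in training has expectation zero).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from scipy import optimize, stats

__all__ = [
    "LMMSpec",
    "LMMFit",
    "fit_lmm",
    "predict_fixed",
    "coef_test",
    "profile_loglik",
]

_LOG_2PI = math.log(2.0 * math.pi)
_LOGG_LO, _LOGG_HI = -23.0, 16.0  # search window for log(variance ratio)


class LMMError(RuntimeError):
    """Fitting failure (rank deficiency, non-convergence, bad inputs)."""


@dataclass
class LMMSpec:
    """Response, fixed design and subject grouping for one fit."""

    response: np.ndarray          # (K,)
    fixed_design: np.ndarray      # (K, p), full column rank
    group_labels: np.ndarray      # (K,) subject id per observation

    def __post_init__(self) -> None:
        self.response = np.asarray(self.response, dtype=float)
        self.fixed_design = np.atleast_2d(np.asarray(self.fixed_design, dtype=float))
        self.group_labels = np.asarray(self.group_labels)
        K = self.response.shape[0]
        if self.fixed_design.shape[0] != K or self.group_labels.shape[0] != K:
            raise LMMError("response, design and group label row counts disagree")
        if not np.all(np.isfinite(self.response)) or not np.all(
            np.isfinite(self.fixed_design)
        ):
            raise LMMError("non-finite values in response or design")


@dataclass
class LMMFit:
    """Fitted random-intercept model.

    ``var_subject`` and ``var_residual`` are on the response scale
    (mg/dL squared for lipid fits); ``aic = 2 (p + 2) - 2 loglik`` counts
    the p fixed effects plus the two variance components.
    """

    fixed_estimates: np.ndarray
    fixed_se: np.ndarray
    var_subject: float
    var_residual: float
    loglik: float
    aic: float
    converged: bool
    boundary: bool              # True when var_subject hit the zero boundary
    method: str
    n_obs: int
    n_groups: int
    cov_fixed: np.ndarray = field(repr=False)

    @property
    def p(self) -> int:
        return len(self.fixed_estimates)

    def to_json(self) -> str:
        d = asdict(self)
        for k in ("fixed_estimates", "fixed_se", "cov_fixed"):
            d[k] = np.asarray(d[k]).tolist()
        return json.dumps(d)

    @classmethod
    def from_json(cls, s: str) -> "LMMFit":
        d = json.loads(s)
        for k in ("fixed_estimates", "fixed_se", "cov_fixed"):
            d[k] = np.asarray(d[k], dtype=float)
        return cls(**d)


class _Profiler:
    """Per-subject sufficient statistics; evaluates the profiled likelihood."""

    def __init__(self, spec: LMMSpec):
        y, X = spec.response, spec.fixed_design
        self.K, self.p = X.shape
        _, inv, counts = np.unique(
            spec.group_labels, return_inverse=True, return_counts=True
        )
        self.n_groups = len(counts)
        self.k_s = counts.astype(float)
        # per-subject sums of design columns and response
        self.A = np.zeros((self.n_groups, self.p))
        np.add.at(self.A, inv, X)
        self.sy = np.bincount(inv, weights=y, minlength=self.n_groups)
        self.XtX = X.T @ X
        self.Xty = X.T @ y
        self.yty = float(y @ y)

    def gls(self, gamma: float):
        """GLS pieces at variance ratio gamma: (beta, XtOX, rss, logdet)."""
        c = gamma / (1.0 + gamma * self.k_s)
        XtOX = self.XtX - self.A.T @ (c[:, None] * self.A)
        XtOy = self.Xty - self.A.T @ (c * self.sy)
        yOy = self.yty - float(c @ (self.sy**2))
        try:
            beta = np.linalg.solve(XtOX, XtOy)
        except np.linalg.LinAlgError as exc:
            raise LMMError("fixed design is rank deficient") from exc
        rss = max(yOy - float(beta @ XtOy), 1e-300)
        logdet = float(np.sum(np.log1p(gamma * self.k_s)))
        return beta, XtOX, rss, logdet

    def loglik(self, gamma: float, method: str) -> float:
        _, XtOX, rss, logdet = self.gls(gamma)
        K, p = self.K, self.p
        if method == "ML":
            s2 = rss / K
            return -0.5 * (K * (_LOG_2PI + math.log(s2) + 1.0) + logdet)
        s2 = rss / (K - p)
        sign, ld_xox = np.linalg.slogdet(XtOX)
        if sign <= 0:
            raise LMMError("X'O^-1 X not positive definite")
        return -0.5 * (
            (K - p) * (_LOG_2PI + math.log(s2) + 1.0) + logdet + ld_xox
        )


def profile_loglik(spec: LMMSpec, gamma: float, method: str = "REML") -> float:
    """Profiled (restricted) log-likelihood at a given variance ratio.

    Exposed for diagnostics and for grid-search validation of the
    optimizer; ``gamma = var_subject / var_residual``.
    """
    return _Profiler(spec).loglik(gamma, method)


def fit_lmm(
    spec: LMMSpec,
    method: str = "REML",
    fixed_variance: tuple[float, float] | None = None,
) -> LMMFit:
    """Fit the random-intercept model.

    Parameters
    ----------
    spec
        Response, fixed design, subject labels.
    method
        ``"ML"`` or ``"REML"``.  ML log-likelihoods make models with the
        same random structure but different fixed terms AIC-comparable.
    fixed_variance
        Optional ``(var_subject, var_residual)``; when given, no variance
        optimization occurs and the GLS fixed effects are computed at
        exactly these components (used by oracles and the fast
        leave-one-out paths).
    """
    if method not in ("ML", "REML"):
        raise LMMError(f"unknown method {method!r}")
    prof = _Profiler(spec)
    K, p = prof.K, prof.p
    if np.linalg.matrix_rank(spec.fixed_design) < p:
        raise LMMError("fixed design is rank deficient")

    if fixed_variance is not None:
        vu, ve = float(fixed_variance[0]), float(fixed_variance[1])
        if ve <= 0 or vu < 0:
            raise LMMError("fixed variance components must be ve > 0, vu >= 0")
        gamma = vu / ve
        beta, XtOX, rss, logdet = prof.gls(gamma)
        ll = -0.5 * (
            K * (_LOG_2PI + math.log(ve)) + logdet + rss / ve
        )
        cov = ve * np.linalg.inv(XtOX)
        return LMMFit(
            fixed_estimates=beta,
            fixed_se=np.sqrt(np.diag(cov)),
            var_subject=vu,
            var_residual=ve,
            loglik=float(ll),
            aic=2.0 * (p + 2) - 2.0 * float(ll),
            converged=True,
            boundary=(vu == 0.0),
            method=f"{method}-fixed",
            n_obs=K,
            n_groups=prof.n_groups,
            cov_fixed=cov,
        )

    if prof.n_groups < 2:
        raise LMMError("need at least 2 subjects")
    if K < p + 2:
        raise LMMError(f"need at least p + 2 = {p + 2} observations, got {K}")

    neg = lambda x: -prof.loglik(math.exp(x), method)
    res = optimize.minimize_scalar(
        neg, bounds=(_LOGG_LO, _LOGG_HI), method="bounded",
        options={"xatol": 1e-8, "maxiter": 500},
    )
    if not res.success:
        raise LMMError(f"variance-ratio optimization failed: {res.message}")
    gamma = math.exp(res.x)
    ll_opt = -res.fun
    ll_zero = prof.loglik(0.0, method)
    boundary = False
    if ll_zero >= ll_opt - 1e-7 or res.x <= _LOGG_LO + 1e-6:
        gamma, ll_opt, boundary = 0.0, max(ll_zero, ll_opt), True

    beta, XtOX, rss, _ = prof.gls(gamma)
    denom = K if method == "ML" else K - p
    s2e = rss / denom
    cov = s2e * np.linalg.inv(XtOX)
    return LMMFit(
        fixed_estimates=beta,
        fixed_se=np.sqrt(np.diag(cov)),
        var_subject=gamma * s2e,
        var_residual=s2e,
        loglik=float(ll_opt),
        aic=2.0 * (p + 2) - 2.0 * float(ll_opt),
        converged=True,
        boundary=boundary,
        method=method,
        n_obs=K,
        n_groups=prof.n_groups,
        cov_fixed=cov,
    )


def predict_fixed(fit: LMMFit, new_design: np.ndarray) -> np.ndarray:
    """Fixed-effects-only prediction ``X_new @ b`` for unseen subjects."""
    new_design = np.atleast_2d(np.asarray(new_design, dtype=float))
    if new_design.shape[1] != fit.p:
        raise LMMError(
            f"design has {new_design.shape[1]} columns, fit expects {fit.p}"
        )
    return new_design @ fit.fixed_estimates


def coef_test(fit: LMMFit, coef_index: int) -> tuple[float, float, float]:
    """Wald z-test of one fixed coefficient: (estimate, se, p)."""
    if not 0 <= coef_index < fit.p:
        raise LMMError(f"coefficient index {coef_index} out of range")
    est = float(fit.fixed_estimates[coef_index])
    se = float(fit.fixed_se[coef_index])
    if se == 0.0:
        raise LMMError("zero standard error; Wald test undefined")
    p = 2.0 * stats.norm.sf(abs(est / se))
    return est, se, float(p)
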