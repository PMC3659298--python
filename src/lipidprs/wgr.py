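"""Bayesian whole-genome regression: lasso (BLR) and ridge (BRR) penalties.

Model for the stacked visit vector:

    y = W theta + X beta + Z u + e,
    e ~ N(0, varE I),  u_s ~ N(0, varU)

with flat priors on the fixed effects theta, and marker-effect priors

* lasso: beta_j | tau2_j, varE ~ N(0, varE tau2_j), tau2_j ~ Exp(lambda^2/2),
  lambda^2 ~ Gamma(shape, rate)  — the double-exponential shrinkage prior
  in its scale-mixture-of-normals form, sampled by Gibbs;
* ridge: beta_j ~ N(0, varB) with a common unknown varB.

varE, varU and varB carry scaled-inverse-chi-square (df, S) priors with
mean S/(df-2).  ``default_priors`` reproduces the elicitation used in the
analysis: with V(y) the training-phenotype variance, h2 = 0.5 the assumed
lipid heritability and MSx the average sum of squares of the training
genotypes,

    varE:  df=5, S = V(y) (1 - h2) (df - 2)
    varU:  df=5, S = V(y) h2 (df - 2)
    BLR:   lambda = sqrt(2 (1 - h2) / h2 * MSx),
           lambda^2 ~ Gamma(shape=2, rate=(shape-1)/lambda^2)
    BRR:   varB: df=5, S = V(y) h2 (df - 2) / MSx

so every variance prior mean equals its natural variance-partition target
and the lambda^2 prior mode sits at the genomic-heritability value.

Predictions for unseen subjects use posterior means of the fixed and
marker effects only: ``Yhat = X beta_bar + W theta_bar``.

The Gibbs sweep runs in a numba kernel.  Dosages are constant within
subject, so marker updates operate on per-subject residual sums (O(n m)
per iteration instead of O(K m)).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

_log = logging.getLogger(__name__)

__all__ = [
    "WGRPriors",
    "MCMCSettings",
    "PosteriorSummary",
    "default_priors",
    "ms_x",
    "fit_blr",
    "fit_brr",
    "fit_wgr",
    "predict_wgr",
]


@dataclass(frozen=True)
class WGRPriors:
    """Hyperparameters of the shrinkage and variance priors."""

    penalty: str                    # "lasso" | "ridge"
    varE_df: float = 5.0
    varE_S: float = 1.0
    varU_df: float = 5.0
    varU_S: float = 1.0
    # lasso hierarchy
    lambda_type: str = "random"
    lambda_value: float = 1.0       # prior-mode lambda (not lambda^2)
    lambda_shape: float = 2.0
    lambda_rate: float = 1.0
    # ridge common marker variance
    varBR_df: float = 5.0
    varBR_S: float = 1.0

    def __post_init__(self) -> None:
        if self.penalty not in ("lasso", "ridge"):
            raise ValueError("penalty must be 'lasso' or 'ridge'")
        for name in ("varE_df", "varU_df", "varBR_df"):
            if getattr(self, name) <= 4.0:
                raise ValueError(f"{name} must exceed 4 so the prior has finite "
                                 "mean and variance")
        for name in ("varE_S", "varU_S", "varBR_S", "lambda_value", "lambda_rate"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class MCMCSettings:
    n_iter: int = 20000
    burnin: int = 5000
    thin: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_iter <= self.burnin:
            raise ValueError("n_iter must exceed burnin")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")


@dataclass
class PosteriorSummary:
    """Posterior means plus thinned post-burn-in chains for diagnostics."""

    marker_effect_means: np.ndarray
    fixed_effect_means: np.ndarray
    varE_mean: float
    varU_mean: float
    lambda_mean: float              # sqrt of posterior mean lambda^2; NaN for ridge
    varB_mean: float                # NaN for lasso
    penalty: str
    n_iter: int
    burnin: int
    thin: int
    seed: int
    chains: dict[str, np.ndarray] = field(repr=False, default_factory=dict)

    def effective_size(self, param: str) -> float:
        """Effective sample size of a stored scalar chain (via arviz)."""
        from arviz import ess

        return float(ess(np.asarray(self.chains[param])))

    def mc_se(self, param: str) -> float:
        """Monte-Carlo standard error of the posterior mean of ``param``."""
        chain = np.asarray(self.chains[param])
        return float(chain.std(ddof=1) / math.sqrt(self.effective_size(param)))

    def mc_se_marker(self, j: int) -> float:
        """Monte-Carlo standard error of one marker effect's posterior mean."""
        from arviz import ess

        chain = np.asarray(self.chains["beta"])[:, j]
        return float(chain.std(ddof=1) / math.sqrt(max(float(ess(chain)), 1.0)))


def ms_x(X: np.ndarray) -> float:
    """Average sum of squares of the training genotypes.

    Sum over markers of the per-marker average squared dosage, equal to
    the row-mean of per-record sums of squares.  Flags an all-zero matrix
    as degenerate.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.size == 0:
        raise ValueError("empty genotype matrix")
    if np.isnan(X).any():
        raise ValueError("complete dosages required for ms_x")
    val = float(np.mean(X**2, axis=0).sum())
    if val == 0.0:
        _log.warning("ms_x is 0 (all-zero genotype matrix): degenerate input")
    return val


def default_priors(var_y: float, h2: float, msx: float, penalty: str) -> WGRPriors:
    """Standard prior elicitation from training-set summaries (see module
    docstring for the formulas)."""
    if var_y <= 0:
        raise ValueError("var_y must be positive")
    if not 0 < h2 < 1:
        raise ValueError("h2 must be in (0, 1)")
    if msx <= 0:
        raise ValueError("ms_x must be positive")
    df = 5.0
    varE_S = var_y * (1.0 - h2) * (df - 2.0)
    varU_S = var_y * h2 * (df - 2.0)
    if penalty == "lasso":
        lam = math.sqrt(2.0 * (1.0 - h2) / h2 * msx)
        shape = 2.0
        return WGRPriors(
            penalty="lasso",
            varE_S=varE_S,
            varU_S=varU_S,
            lambda_value=lam,
            lambda_shape=shape,
            lambda_rate=(shape - 1.0) / lam**2,
        )
    if penalty == "ridge":
        return WGRPriors(
            penalty="ridge",
            varE_S=varE_S,
            varU_S=varU_S,
            varBR_S=var_y * h2 * (df - 2.0) / msx,
        )
    raise ValueError("penalty must be 'lasso' or 'ridge'")


# ---------------------------------------------------------------------------
# Gibbs kernel
# ---------------------------------------------------------------------------


@njit(cache=True)
def _inv_gaussian(mu, lam):  # pragma: no cover - exercised through the kernel
    v = np.random.standard_normal()
    z = v * v
    x = mu + mu * mu * z / (2.0 * lam) - mu / (2.0 * lam) * math.sqrt(
        4.0 * mu * lam * z + mu * mu * z * z
    )
    if x <= 0.0:
        x = 1e-12
    if np.random.random_sample() <= mu / (mu + x):
        return x
    return mu * mu / x


@njit(cache=True)
def _gibbs_kernel(
    y, W, L, XsT, subj, k_s,
    lasso, include_random,
    varE_df, varE_S, varU_df, varU_S, varBR_df, varBR_S,
    lam2_shape, lam2_rate, lam2_init,
    fixE, fixU, fixL2, fixB,
    n_iter, burnin, thin, seed,
):
    np.random.seed(seed)
    K = y.shape[0]
    p = W.shape[1]
    m = XsT.shape[0]
    n = k_s.shape[0]

    xtx = np.empty(m)
    for j in range(m):
        acc = 0.0
        for s in range(n):
            acc += k_s[s] * XsT[j, s] * XsT[j, s]
        xtx[j] = acc

    beta = np.zeros(m)
    theta = np.zeros(p)
    u = np.zeros(n)
    tau2 = np.ones(m)
    lam2 = lam2_init if fixL2 <= 0.0 else fixL2
    varE = varE_S / (varE_df - 2.0) if fixE <= 0.0 else fixE
    varU = varU_S / (varU_df - 2.0) if fixU <= 0.0 else fixU
    varB = varBR_S / (varBR_df - 2.0) if fixB <= 0.0 else fixB

    e = y.copy()  # residual y - W theta - X beta - Z u (all start at zero)

    n_keep = (n_iter - burnin + thin - 1) // thin
    c_beta = np.zeros((n_keep, m))
    c_theta = np.zeros((n_keep, p))
    c_varE = np.zeros(n_keep)
    c_varU = np.zeros(n_keep)
    c_lam2 = np.zeros(n_keep)
    c_varB = np.zeros(n_keep)
    kept = 0
    status = 0

    es = np.zeros(n)
    z = np.zeros(p)
    for it in range(n_iter):
        # --- fixed effects (flat prior): theta ~ N((W'W)^-1 W'r, varE (W'W)^-1)
        r_t = W.T @ e + (W.T @ W) @ theta  # W'(e + W theta)
        # solve L L' mu = r_t
        mu_t = np.linalg.solve(L, r_t)
        mu_t = np.linalg.solve(L.T, mu_t)
        for q in range(p):
            z[q] = np.random.standard_normal()
        theta_new = mu_t + math.sqrt(varE) * np.linalg.solve(L.T, z)
        delta_t = W @ (theta_new - theta)
        for t in range(K):
            e[t] -= delta_t[t]
        theta = theta_new

        # --- marker effects via per-subject residual sums
        for s in range(n):
            es[s] = 0.0
        for t in range(K):
            es[subj[t]] += e[t]
        dscore = np.zeros(n)
        for j in range(m):
            xe = 0.0
            for s in range(n):
                xe += XsT[j, s] * es[s]
            num = xe + xtx[j] * beta[j]
            if lasso:
                prec = 1.0 / tau2[j]
            else:
                prec = varE / varB
            d = xtx[j] + prec
            mean = num / d
            sd = math.sqrt(varE / d)
            b_new = mean + sd * np.random.standard_normal()
            db = b_new - beta[j]
            beta[j] = b_new
            if db != 0.0:
                for s in range(n):
                    step = db * XsT[j, s]
                    es[s] -= step * k_s[s]
                    dscore[s] += step
        for t in range(K):
            e[t] -= dscore[subj[t]]

        # --- lasso hierarchy
        if lasso:
            sum_tau2 = 0.0
            for j in range(m):
                b2 = beta[j] * beta[j]
                if b2 < 1e-12 * varE:
                    b2 = 1e-12 * varE
                mu_ig = math.sqrt(lam2 * varE / b2)
                if mu_ig > 1e8:
                    mu_ig = 1e8
                inv_t2 = _inv_gaussian(mu_ig, lam2)
                t2 = 1.0 / inv_t2
                if t2 < 1e-12:
                    t2 = 1e-12
                tau2[j] = t2
                sum_tau2 += t2
            if fixL2 <= 0.0:
                lam2 = np.random.gamma(
                    lam2_shape + m, 1.0 / (lam2_rate + 0.5 * sum_tau2)
                )
        else:
            if fixB <= 0.0:
                sum_b2 = 0.0
                for j in range(m):
                    sum_b2 += beta[j] * beta[j]
                varB = (varBR_S + sum_b2) / np.random.chisquare(varBR_df + m)

        # --- subject random intercepts
        if include_random:
            for s in range(n):
                es[s] = 0.0
            for t in range(K):
                es[subj[t]] += e[t]
            for s in range(n):
                denom = k_s[s] + varE / varU
                mean_u = (es[s] + k_s[s] * u[s]) / denom
                sd_u = math.sqrt(varE / denom)
                u_new = mean_u + sd_u * np.random.standard_normal()
                es[s] = u_new - u[s]  # reuse as delta
                u[s] = u_new
            for t in range(K):
                e[t] -= es[subj[t]]
            if fixU <= 0.0:
                sum_u2 = 0.0
                for s in range(n):
                    sum_u2 += u[s] * u[s]
                varU = (varU_S + sum_u2) / np.random.chisquare(varU_df + n)

        # --- residual variance
        if fixE <= 0.0:
            sse = 0.0
            for t in range(K):
                sse += e[t] * e[t]
            dfE = varE_df + K
            if lasso:
                for j in range(m):
                    sse += beta[j] * beta[j] / tau2[j]
                dfE += m
            varE = (varE_S + sse) / np.random.chisquare(dfE)

        if not (math.isfinite(varE) and math.isfinite(varU) and math.isfinite(lam2)):
            status = it + 1
            break

        if it >= burnin and (it - burnin) % thin == 0:
            for j in range(m):
                c_beta[kept, j] = beta[j]
            for q in range(p):
                c_theta[kept, q] = theta[q]
            c_varE[kept] = varE
            c_varU[kept] = varU
            c_lam2[kept] = lam2
            c_varB[kept] = varB
            kept += 1

    return status, kept, c_beta, c_theta, c_varE, c_varU, c_lam2, c_varB


# ---------------------------------------------------------------------------
# Public fitting interface
# ---------------------------------------------------------------------------


def fit_wgr(
    y: np.ndarray,
    W: np.ndarray,
    Xs: np.ndarray,
    subj_of_obs: np.ndarray | None,
    priors: WGRPriors,
    mcmc: MCMCSettings,
    include_random: bool = True,
    fix_varE: float | None = None,
    fix_varU: float | None = None,
    fix_lambda2: float | None = None,
    fix_varB: float | None = None,
) -> PosteriorSummary:
    """Run the Gibbs sampler.

    Parameters
    ----------
    y, W
        Observation-level response and fixed-covariate design.
    Xs
        Subject-level dosage matrix (n_subjects x m), complete (no NaN).
    subj_of_obs
        Maps each observation to its row of ``Xs``.  ``None`` means one
        observation per row of ``Xs`` (no repeated measures).
    include_random
        Include the per-subject random intercept.  Disable for flat
        (single-observation) designs, e.g. in conjugate validation.
    fix_*
        Freeze a variance/regularization parameter at a known value
        instead of sampling it (validation hooks).
    """
    y = np.asarray(y, dtype=float)
    W = np.atleast_2d(np.asarray(W, dtype=float))
    Xs = np.atleast_2d(np.asarray(Xs, dtype=float))
    if subj_of_obs is None:
        subj_of_obs = np.arange(len(y))
    subj = np.asarray(subj_of_obs, dtype=np.int64)
    if np.isnan(Xs).any():
        raise ValueError("complete dosages required (impute first)")
    if W.shape[0] != len(y) or subj.shape[0] != len(y):
        raise ValueError("row counts of y, W and subj_of_obs disagree")
    n = Xs.shape[0]
    if subj.min() < 0 or subj.max() >= n:
        raise ValueError("subject indices out of range")

    k_s = np.bincount(subj, minlength=n).astype(float)
    L = np.linalg.cholesky(W.T @ W)
    lasso = priors.penalty == "lasso"

    status, kept, c_beta, c_theta, c_varE, c_varU, c_lam2, c_varB = _gibbs_kernel(
        y, W, L, np.ascontiguousarray(Xs.T), subj, k_s,
        lasso, include_random,
        priors.varE_df, priors.varE_S, priors.varU_df, priors.varU_S,
        priors.varBR_df, priors.varBR_S,
        priors.lambda_shape, priors.lambda_rate, priors.lambda_value**2,
        -1.0 if fix_varE is None else float(fix_varE),
        -1.0 if fix_varU is None else float(fix_varU),
        -1.0 if fix_lambda2 is None else float(fix_lambda2),
        -1.0 if fix_varB is None else float(fix_varB),
        mcmc.n_iter, mcmc.burnin, mcmc.thin, mcmc.seed % (2**31),
    )
    if status != 0:
        raise RuntimeError(f"non-finite draw at iteration {status - 1}")

    chains = {
        "beta": c_beta[:kept],
        "theta": c_theta[:kept],
        "varE": c_varE[:kept],
        "varU": c_varU[:kept],
    }
    if lasso:
        chains["lambda2"] = c_lam2[:kept]
    else:
        chains["varB"] = c_varB[:kept]
    return PosteriorSummary(
        marker_effect_means=c_beta[:kept].mean(axis=0),
        fixed_effect_means=c_theta[:kept].mean(axis=0),
        varE_mean=float(c_varE[:kept].mean()),
        varU_mean=float(c_varU[:kept].mean()) if include_random else float("nan"),
        lambda_mean=float(np.sqrt(c_lam2[:kept].mean())) if lasso else float("nan"),
        varB_mean=float(c_varB[:kept].mean()) if not lasso else float("nan"),
        penalty=priors.penalty,
        n_iter=mcmc.n_iter,
        burnin=mcmc.burnin,
        thin=mcmc.thin,
        seed=mcmc.seed,
        chains=chains,
    )


def fit_blr(y, W, Xs, subj_of_obs, priors: WGRPriors, mcmc: MCMCSettings,
            **kwargs) -> PosteriorSummary:
    """Bayesian lasso regression (double-exponential marker shrinkage)."""
    if priors.penalty != "lasso":
        raise ValueError("fit_blr requires lasso priors")
    return fit_wgr(y, W, Xs, subj_of_obs, priors, mcmc, **kwargs)


def fit_brr(y, W, Xs, subj_of_obs, priors: WGRPriors, mcmc: MCMCSettings,
            **kwargs) -> PosteriorSummary:
    """Bayesian ridge regression (common Gaussian marker shrinkage)."""
    if priors.penalty != "ridge":
        raise ValueError("fit_brr requires ridge priors")
    return fit_wgr(y, W, Xs, subj_of_obs, priors, mcmc, **kwargs)


def predict_wgr(
    post: PosteriorSummary, X_new: np.ndarray, W_new: np.ndarray
) -> np.ndarray:
    """Posterior-mean prediction ``X beta_bar + W theta_bar`` (random
    subject effects excluded — unseen subjects have expectation zero)."""
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    W_new = np.atleast_2d(np.asarray(W_new, dtype=float))
    if X_new.shape[1] != len(post.marker_effect_means):
        raise ValueError("X_new column count does not match marker effects")
    if W_new.shape[1] != len(post.fixed_effect_means):
        raise ValueError("W_new column count does not match fixed effects")
    return X_new @ post.marker_effect_means + W_new @ post.fixed_effect_means


def geweke_z(chain: np.ndarray, first: float = 0.1, last: float = 0.5) -> float:
    """Geweke-style drift statistic between early and late chain segments.

    Approximately N(0,1) for a converged, well-mixed chain; segment
    variances are corrected by the effective sample size.
    """
    from arviz import ess

    chain = np.asarray(chain, dtype=float)
    a = chain[: int(len(chain) * first)]
    b = chain[-int(len(chain) * last):]
    va = a.var(ddof=1) / max(float(ess(a)), 1.0)
    vb = b.var(ddof=1) / max(float(ess(b)), 1.0)
    return float((a.mean() - b.mean()) / math.sqrt(va + vb))
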