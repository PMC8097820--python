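"""Vectorized negative-binomial log-linear models for count matrices.

Fits, for every feature (peak or gene) simultaneously, the NB2 model

    y_fs ~ NB(mu_fs, alpha_f),   log mu_fs = x_s' beta_f + offset_s

with a shared design matrix across features, which allows the IRLS normal
equations to be solved as one batched linear solve per iteration.  Dispersion
is estimated per feature by Cox–Reid adjusted profile likelihood, then shrunk
toward a smooth (lowess) mean–dispersion trend on the log scale — an
empirical-Bayes style moderation that stabilizes small-sample Wald tests.
Inference on a coefficient is a Wald z-test from the observed Fisher
information at the final fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln
from scipy.stats import norm, t as t_dist
from statsmodels.nonparametric.smoothers_lowess import lowess

_ETA_CLIP = 30.0
_ALPHA_MIN, _ALPHA_MAX = 1e-8, 20.0


@dataclass
class NBFit:
    beta: np.ndarray               # (F, P)
    alpha: np.ndarray              # (F,) final (shrunk) dispersions
    alpha_ml: np.ndarray           # (F,) per-feature ML dispersions
    mu: np.ndarray                 # (F, S)
    se: np.ndarray                 # (F, P) Wald standard errors
    converged: np.ndarray          # (F,) bool
    residual_df: int = 0
    design_columns: list = field(default_factory=list)

    def wald_test(self, coef: int | str,
                  reference: str = "t") -> tuple[np.ndarray, np.ndarray]:
        """Two-sided Wald p-value and statistic for one coefficient.

        The default reference is a t distribution with residual degrees of
        freedom (samples minus design columns), a small-sample moderation of
        the asymptotic normal Wald test; pass ``reference='normal'`` for the
        plain z test.
        """
        j = (
            self.design_columns.index(coef)
            if isinstance(coef, str)
            else int(coef)
        )
        z = self.beta[:, j] / self.se[:, j]
        if reference == "t" and self.residual_df > 0:
            p = 2.0 * t_dist.sf(np.abs(z), df=self.residual_df)
        else:
            p = 2.0 * norm.sf(np.abs(z))
        return p, z


def _irls(Y, X, offset, alpha, beta0=None, maxiter=50, tol=1e-8):
    """Batched IRLS for fixed per-feature dispersion.  Returns beta, mu, XtWX."""
    F, S = Y.shape
    P = X.shape[1]
    if beta0 is None:
        z0 = np.log(Y + 0.5) - offset
        beta = np.linalg.lstsq(X, z0.T, rcond=None)[0].T
    else:
        beta = beta0.copy()
    ridge = 1e-10 * np.eye(P)
    a = alpha[:, None]
    converged = np.zeros(F, dtype=bool)
    mu = None
    for _ in range(maxiter):
        eta = np.clip(beta @ X.T + offset, -_ETA_CLIP, _ETA_CLIP)
        mu = np.exp(eta)
        W = mu / (1.0 + a * mu)
        z = eta - offset + (Y - mu) / mu
        XtWX = np.einsum("sp,fs,sq->fpq", X, W, X)
        XtWz = np.einsum("sp,fs->fp", X, W * z)
        new_beta = np.linalg.solve(XtWX + ridge, XtWz[..., None])[..., 0]
        delta = np.max(np.abs(new_beta - beta), axis=1)
        beta = new_beta
        converged |= delta < tol
        if converged.all():
            break
    eta = np.clip(beta @ X.T + offset, -_ETA_CLIP, _ETA_CLIP)
    mu = np.exp(eta)
    W = mu / (1.0 + a * mu)
    XtWX = np.einsum("sp,fs,sq->fpq", X, W, X)
    return beta, mu, XtWX, converged


def _cr_profile_loglik(Y, mu, X, log_alpha):
    """Cox–Reid adjusted NB profile log-likelihood, vectorized over features.

    ``log_alpha`` has shape (F,) — one candidate per feature.
    """
    a = np.exp(log_alpha)[:, None]
    inv_a = 1.0 / a
    ll = (
        gammaln(Y + inv_a)
        - gammaln(inv_a)
        - gammaln(Y + 1.0)
        + inv_a * np.log(inv_a / (inv_a + mu))
        + Y * np.log(mu / (inv_a + mu) + 1e-300)
    ).sum(axis=1)
    W = mu / (1.0 + a * mu)
    XtWX = np.einsum("sp,fs,sq->fpq", X, W, X)
    sign, logdet = np.linalg.slogdet(XtWX + 1e-10 * np.eye(X.shape[1]))
    return ll - 0.5 * logdet


def estimate_dispersion_ml(Y, mu, X, grid_size: int = 25) -> np.ndarray:
    """Per-feature dispersion by CR-adjusted profile ML (grid + parabolic refine)."""
    F = Y.shape[0]
    grid = np.linspace(np.log(_ALPHA_MIN), np.log(_ALPHA_MAX), grid_size)
    lls = np.empty((F, grid_size))
    for k, la in enumerate(grid):
        lls[:, k] = _cr_profile_loglik(Y, mu, X, np.full(F, la))
    best = np.argmax(lls, axis=1)
    log_alpha = grid[best]
    # parabolic refinement around the best grid point
    inner = (best > 0) & (best < grid_size - 1)
    if inner.any():
        idx = np.where(inner)[0]
        b = best[idx]
        y0, y1, y2 = lls[idx, b - 1], lls[idx, b], lls[idx, b + 1]
        h = grid[1] - grid[0]
        denom = y0 - 2 * y1 + y2
        shift = np.where(np.abs(denom) > 1e-12, 0.5 * h * (y0 - y2) / denom, 0.0)
        log_alpha[idx] = grid[b] + np.clip(shift, -h, h)
    return np.exp(log_alpha)


def dispersion_trend(alpha_ml, base_mean, frac: float = 0.4):
    """Smooth mean–dispersion trend: lowess of log alpha on log mean."""
    ok = (base_mean > 0) & np.isfinite(alpha_ml) & (alpha_ml > _ALPHA_MIN * 2)
    if ok.sum() < 10:
        med = np.median(np.log(np.clip(alpha_ml, _ALPHA_MIN, None)))
        return np.full_like(alpha_ml, np.exp(med))
    x = np.log(base_mean[ok])
    y = np.log(alpha_ml[ok])
    sm = lowess(y, x, frac=frac, it=2, return_sorted=True)
    xs, ys = sm[:, 0], sm[:, 1]
    xq = np.log(np.clip(base_mean, np.exp(xs[0]), np.exp(xs[-1])))
    return np.exp(np.interp(xq, xs, ys))


def fit_nb_glm(
    Y: np.ndarray,
    X: np.ndarray,
    offset: np.ndarray | None = None,
    design_columns: list | None = None,
    shrink_weight: float = 0.5,
    trend_frac: float = 0.4,
) -> NBFit:
    """Fit the NB log-linear model to every row of ``Y``.

    Parameters
    ----------
    Y : (features, samples) count matrix (non-negative; real-valued allowed
        for covariate-adjusted pseudo-counts).
    X : (samples, p) design matrix, shared across features.
    offset : per-sample log offset (e.g. log normalization factor), or a
        (features, samples) array.
    shrink_weight : weight of the lowess trend in the log-scale dispersion
        moderation; 0 keeps the per-feature ML estimate, 1 uses the trend.
    """
    Y = np.asarray(Y, dtype=float)
    X = np.asarray(X, dtype=float)
    F, S = Y.shape
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is not full rank")
    if offset is None:
        offset = np.zeros(S)
    offset = np.broadcast_to(np.asarray(offset, dtype=float), (F, S)) \
        if np.ndim(offset) == 1 else np.asarray(offset, dtype=float)

    # 1) initial fit with a rough method-of-moments dispersion
    norm_y = Y / np.exp(offset)
    base_mean = norm_y.mean(axis=1)
    m = np.clip(base_mean, 1e-8, None)
    v = norm_y.var(axis=1, ddof=1)
    alpha0 = np.clip((v - m) / m**2, 0.01, _ALPHA_MAX)
    beta, mu, _, _ = _irls(Y, X, offset, alpha0)

    # 2) per-feature ML dispersion given the fitted means, then trend shrinkage
    alpha_ml = estimate_dispersion_ml(Y, mu, X)
    trend = dispersion_trend(alpha_ml, base_mean, frac=trend_frac)
    log_a = (1.0 - shrink_weight) * np.log(alpha_ml) + shrink_weight * np.log(trend)
    alpha = np.clip(np.exp(log_a), _ALPHA_MIN, _ALPHA_MAX)

    # 3) final fit and Wald SEs at the moderated dispersion
    beta, mu, XtWX, converged = _irls(Y, X, offset, alpha, beta0=beta)
    cov = np.linalg.inv(XtWX + 1e-10 * np.eye(X.shape[1]))
    se = np.sqrt(np.maximum(np.diagonal(cov, axis1=1, axis2=2), 0.0))
    all_zero = Y.sum(axis=1) == 0
    converged = converged & ~all_zero
    return NBFit(
        beta=beta,
        alpha=alpha,
        alpha_ml=alpha_ml,
        mu=mu,
        se=se,
        converged=converged,
        residual_df=max(S - X.shape[1], 0),
        design_columns=design_columns or [f"x{j}" for j in range(X.shape[1])],
    )


def build_design_matrix(metadata, covariates, group_col: str = "group",
                        reference: str = "control"):
    """Intercept + group indicator (+ centered/dummy covariates).

    Categorical covariates are dummy-coded dropping the first level;
    continuous covariates are mean-centered.  Returns (X, column names).
    """
    import pandas as pd

    cols = {"intercept": np.ones(len(metadata))}
    levels = set(metadata[group_col])
    other = sorted(levels - {reference})
    if len(other) != 1 or reference not in levels:
        raise ValueError("group must have exactly two levels incl. the reference")
    cols[f"{group_col}_{other[0]}"] = (metadata[group_col] == other[0]).astype(float)
    for cov in covariates:
        s = metadata[cov]
        if s.dtype.kind in "OUSb" or isinstance(s.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(s, prefix=cov, drop_first=True)
            for c in dummies.columns:
                cols[c] = dummies[c].astype(float).to_numpy()
        else:
            cols[cov] = (s - s.mean()).to_numpy(dtype=float)
    X = np.column_stack(list(cols.values()))
    return X, list(cols.keys())
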