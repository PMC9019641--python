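"""Proportional-odds (cumulative logit) ordinal regression.

The model for an ordered outcome ``Y`` in categories ``0 < 1 < ... < K-1``
with covariate row ``x`` is::

    logit P(Y <= k | x) = theta_k - x . beta,   k = 0 .. K-2

with strictly increasing thresholds ``theta`` and a single coefficient
vector ``beta`` shared across thresholds (the proportional-odds
assumption).  Positive coefficients shift probability mass toward
higher (more severe) categories; ``exp(beta_j)`` is the cumulative odds
ratio per unit of covariate ``j``.

Fitting is by Newton-Raphson on the exact log-likelihood with analytic
gradient and Hessian, step-halving to keep the thresholds ordered and
the likelihood non-decreasing, and standard errors from the observed
information matrix.  With two outcome categories the model is exactly
binary logistic regression.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit
from scipy.stats import norm

__all__ = [
    "SeparationError",
    "OrdinalFit",
    "fit_proportional_odds",
    "simulate_proportional_odds",
]

_TINY = 1e-300


class SeparationError(ValueError):
    """Raised when the likelihood diverges (complete/quasi-complete separation)."""


@dataclass(frozen=True)
class OrdinalFit:
    """A fitted proportional-odds model.

    On non-convergence only ``loglik``, ``converged`` and ``n_iter`` are
    populated; the parameter estimates are withheld (``None``).
    """

    thresholds: np.ndarray | None
    coef: np.ndarray | None
    se_thresholds: np.ndarray | None
    se_coef: np.ndarray | None
    loglik: float
    converged: bool
    n_iter: int
    n_obs: int
    n_categories: int

    @property
    def t_values(self) -> np.ndarray:
        """Wald statistics ``coef / se`` (inf SEs give 0)."""
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(np.isfinite(self.se_coef), self.coef / self.se_coef, 0.0)
        return t

    @property
    def odds_ratios(self) -> np.ndarray:
        """``exp(coef)``, the cumulative odds ratios."""
        return np.exp(self.coef)

    def or_ci(self, level: float = 0.95) -> np.ndarray:
        """Wald confidence intervals for the odds ratios, shape (p, 2)."""
        z = norm.ppf(0.5 + level / 2.0)
        lo = np.exp(self.coef - z * self.se_coef)
        hi = np.exp(self.coef + z * self.se_coef)
        return np.column_stack([lo, hi])

    def summary_dict(self) -> dict:
        """JSON-friendly summary of the fit."""
        ci = self.or_ci()
        return {
            "thresholds": [float(v) for v in self.thresholds],
            "se_thresholds": [float(v) for v in self.se_thresholds],
            "coef": [float(v) for v in self.coef],
            "se_coef": [float(v) for v in self.se_coef],
            "t_values": [float(v) for v in self.t_values],
            "odds_ratio": [float(v) for v in self.odds_ratios],
            "or_ci_95": [[float(a), float(b)] for a, b in ci],
            "loglik": float(self.loglik),
            "converged": self.converged,
            "n_iter": self.n_iter,
            "n_obs": self.n_obs,
            "n_categories": self.n_categories,
        }


def _prepare(y, X):
    y = np.asarray(y)
    if y.ndim != 1:
        raise ValueError("y must be one-dimensional")
    n = y.shape[0]
    if X is None:
        X = np.zeros((n, 0))
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[0] != n:
        raise ValueError("X and y must have the same number of rows")
    cats = np.unique(y)
    if cats.size < 2:
        raise ValueError("outcome must have at least 2 observed categories")
    codes = np.searchsorted(cats, y)
    return codes, X, int(cats.size)


def _loglik_grad_hess(theta, beta, X, y, K, want_derivs=True):
    """Log-likelihood and, optionally, analytic gradient and Hessian."""
    n, p = X.shape
    xb = X @ beta
    up_valid = y < K - 1
    lo_valid = y > 0

    eta_up = np.where(up_valid, theta[np.minimum(y, K - 2)] - xb, 0.0)
    s_up = np.where(up_valid, expit(eta_up), 1.0)
    g_up = np.where(up_valid, s_up * (1.0 - s_up), 0.0)

    eta_lo = np.where(lo_valid, theta[np.maximum(y - 1, 0)] - xb, 0.0)
    s_lo = np.where(lo_valid, expit(eta_lo), 0.0)
    g_lo = np.where(lo_valid, s_lo * (1.0 - s_lo), 0.0)

    pi = np.clip(s_up - s_lo, _TINY, None)
    ll = float(np.log(pi).sum())
    if not want_derivs:
        return ll, None, None

    du = g_up / pi          # d loglik / d eta_up, per observation
    dl = -g_lo / pi         # d loglik / d eta_lo
    h_up = g_up * (1.0 - 2.0 * s_up)
    h_lo = g_lo * (1.0 - 2.0 * s_lo)

    # second derivatives in eta space
    auu = h_up / pi - du**2
    all_ = -h_lo / pi - dl**2
    aul = g_up * g_lo / pi**2

    m = K - 1
    grad = np.zeros(m + p)
    hess = np.zeros((m + p, m + p))

    for j in range(m):
        mask_up = y == j        # these obs have eta_up = theta_j - xb
        mask_lo = y == j + 1    # these obs have eta_lo = theta_j - xb
        grad[j] = du[mask_up].sum() + dl[mask_lo].sum()
        hess[j, j] = auu[mask_up].sum() + all_[mask_lo].sum()
        if j + 1 < m:
            # obs with y == j+1 couple theta_{j+1} (up) with theta_j (lo)
            cross = aul[mask_lo].sum()
            hess[j, j + 1] += cross
            hess[j + 1, j] += cross
        if p:
            w = (
                auu * mask_up
                + aul * (mask_up & lo_valid)
                + all_ * mask_lo
                + aul * (mask_lo & up_valid)
            )
            block = -(X.T @ w)
            hess[j, m:] += block
            hess[m:, j] += block
    if p:
        grad[m:] = -(X.T @ (du + dl))
        a_beta = auu + all_ + 2.0 * aul
        hess[m:, m:] = X.T @ (X * a_beta[:, None])
    return ll, grad, hess


def fit_proportional_odds(
    y,
    X=None,
    *,
    tol: float = 1e-8,
    max_iter: int = 100,
    max_abs_param: float = 30.0,
) -> OrdinalFit:
    """Fit a proportional-odds model by Newton-Raphson maximum likelihood.

    Parameters
    ----------
    y
        Ordered outcome per observation; any strictly ordered integer
        coding works (categories are ranked by value).  At least two
        categories must be observed.
    X
        Design matrix ``(n, p)`` of covariates, without an intercept
        column (the thresholds play that role).  ``None`` or a zero-
        column matrix fits the intercept-only model, whose thresholds
        are the empirical cumulative logits.
    tol
        Convergence tolerance on the maximum absolute gradient entry.
    max_abs_param
        Divergence guard: if any parameter passes this magnitude a
        :class:`SeparationError` is raised, which is the usual symptom
        of complete or quasi-complete separation.

    Notes
    -----
    A covariate that is identically zero carries no information: its
    coefficient stays 0 and its standard error is reported as ``inf``
    (the observed information is singular; the Newton step then uses the
    pseudo-inverse).
    """
    y, X, K = _prepare(y, X)
    n, p = X.shape
    m = K - 1

    freqs = np.bincount(y, minlength=K) / n
    cum = np.clip(np.cumsum(freqs)[:-1], 1e-10, 1 - 1e-10)
    theta = np.log(cum / (1.0 - cum))
    beta = np.zeros(p)

    ll, grad, hess = _loglik_grad_hess(theta, beta, X, y, K)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        if np.max(np.abs(grad)) < tol:
            converged = True
            it -= 1
            break
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.pinv(hess) @ grad
        if not np.all(np.isfinite(step)):
            step = np.linalg.pinv(hess) @ grad
        lam = 1.0
        accepted = False
        for _ in range(40):
            theta_new = theta - lam * step[:m]
            beta_new = beta - lam * step[m:]
            if np.all(np.diff(theta_new) > 0):
                ll_new, _, _ = _loglik_grad_hess(
                    theta_new, beta_new, X, y, K, want_derivs=False
                )
                if ll_new >= ll - 1e-12:
                    theta, beta, ll = theta_new, beta_new, ll_new
                    accepted = True
                    break
            lam *= 0.5
        if not accepted:
            break
        if max(np.max(np.abs(theta)), np.max(np.abs(beta), initial=0.0)) > max_abs_param:
            raise SeparationError(
                "parameter estimates diverged; the data are completely or "
                "quasi-completely separated"
            )
        ll, grad, hess = _loglik_grad_hess(theta, beta, X, y, K)
    else:
        it = max_iter
    if not converged and np.max(np.abs(grad)) < tol:
        converged = True

    if not converged:
        return OrdinalFit(
            thresholds=None,
            coef=None,
            se_thresholds=None,
            se_coef=None,
            loglik=ll,
            converged=False,
            n_iter=it,
            n_obs=n,
            n_categories=K,
        )

    info = -hess
    diag = np.diag(info)
    degenerate = diag < 1e-12
    with np.errstate(all="ignore"):
        try:
            cov = np.linalg.inv(info)
        except np.linalg.LinAlgError:
            cov = np.linalg.pinv(info)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    se[degenerate] = np.inf
    return OrdinalFit(
        thresholds=theta,
        coef=beta,
        se_thresholds=se[:m],
        se_coef=se[m:],
        loglik=ll,
        converged=True,
        n_iter=it,
        n_obs=n,
        n_categories=K,
    )


def simulate_proportional_odds(thresholds, coef, X, rng) -> np.ndarray:
    """Draw ordinal outcomes ``0..K-1`` from a proportional-odds model.

    ``thresholds`` must be strictly increasing (length ``K-1``); ``X``
    is the ``(n, p)`` design matrix and ``rng`` a NumPy generator.
    """
    thresholds = np.asarray(thresholds, dtype=float)
    if np.any(np.diff(thresholds) <= 0):
        raise ValueError("thresholds must be strictly increasing")
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    xb = X @ np.asarray(coef, dtype=float)
    cum = expit(thresholds[None, :] - xb[:, None])  # (n, K-1)
    u = rng.random(X.shape[0])
    return (u[:, None] > cum).sum(axis=1)
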