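"""Small dedicated binomial-logit fitter.

The enrichment machinery refits nested logistic models tens of thousands of
times inside permutation loops, so the Newton–Raphson maximum-likelihood
fit and the Firth (Jeffreys-prior penalized) fallback for separated data
are implemented directly on numpy arrays. Correctness is cross-checked
against statsmodels GLM in the test suite.

Log-likelihood (saturated-model reference is 0 for binary outcomes):

    l(beta) = sum_i [ y_i eta_i - log(1 + exp(eta_i)) ],   eta = X beta

Firth's penalty adds 0.5 * log det(X' W X), removing the first-order bias
and guaranteeing finite estimates under complete separation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

_MAX_ABS_BETA = 10.0  # |beta| beyond this on these designs => separation


@dataclass(frozen=True)
class LogisticFit:
    beta: np.ndarray
    loglik: float  # penalized loglik for method="penalized"
    converged: bool
    separated: bool
    method: str  # "mle" or "penalized"


def _loglik(eta: np.ndarray, y: np.ndarray) -> float:
    return float(y @ eta - np.logaddexp(0.0, eta).sum())


def _mu(eta: np.ndarray) -> np.ndarray:
    out = np.empty_like(eta)
    pos = eta >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-eta[pos]))
    ex = np.exp(eta[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def fit_mle(
    X: np.ndarray, y: np.ndarray, max_iter: int = 40, tol: float = 1e-10
) -> LogisticFit:
    """Newton–Raphson MLE with step-halving.

    Flags ``separated`` when the iteration diverges (coefficients running
    to infinity) or fails to converge — callers then refit with Firth.
    """
    n, p = X.shape
    beta = np.zeros(p)
    eta = X @ beta
    ll = _loglik(eta, y)
    converged = False
    for _ in range(max_iter):
        mu = _mu(eta)
        w = mu * (1.0 - mu)
        grad = X.T @ (y - mu)
        # a tight gradient criterion: separated fits plateau in likelihood
        # while the gradient stays structurally nonzero until |beta| has
        # drifted past any plausible finite estimate
        if np.abs(grad).max() < 1e-8:
            converged = True
            break
        info = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(info + 1e-12 * np.eye(p), grad)
        except np.linalg.LinAlgError:
            return LogisticFit(beta, ll, False, True, "mle")
        # step-halving keeps the likelihood monotone
        new_ll = -np.inf
        for _ in range(25):
            cand = beta + step
            cand_eta = X @ cand
            new_ll = _loglik(cand_eta, y)
            if new_ll >= ll - 1e-12:
                break
            step *= 0.5
        beta, eta, ll = beta + step, X @ (beta + step), new_ll
        if np.abs(beta).max() > 3 * _MAX_ABS_BETA:
            break  # clearly diverging
    separated = (not converged) or bool(np.abs(beta).max() > _MAX_ABS_BETA)
    return LogisticFit(beta, ll, converged, separated, "mle")


def fit_firth(
    X: np.ndarray, y: np.ndarray, max_iter: int = 120, tol: float = 1e-9
) -> LogisticFit:
    """Firth bias-reduced logistic fit (penalized likelihood).

    Uses the modified score U*_r = sum_i (y_i - mu_i + h_i (1/2 - mu_i)) x_ir
    with h the hat-matrix diagonal, and step-halving on the penalized
    log-likelihood.
    """
    n, p = X.shape
    beta = np.zeros(p)

    def penalized(beta: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
        eta = X @ beta
        mu = _mu(eta)
        w = np.clip(mu * (1.0 - mu), 1e-12, None)
        info = (X * w[:, None]).T @ X
        sign, logdet = np.linalg.slogdet(info)
        pll = _loglik(eta, y) + 0.5 * (logdet if sign > 0 else -np.inf)
        return pll, mu, info

    pll, mu, info = penalized(beta)
    converged = False
    for _ in range(max_iter):
        w = np.clip(mu * (1.0 - mu), 1e-12, None)
        xw = X * w[:, None]
        try:
            info_inv = np.linalg.inv(info + 1e-12 * np.eye(p))
        except np.linalg.LinAlgError:
            break
        h = np.einsum("ij,jk,ik->i", X, info_inv, xw)
        score = X.T @ (y - mu + h * (0.5 - mu))
        step = info_inv @ score
        new_pll = -np.inf
        for _ in range(25):
            cand = beta + step
            new_pll, new_mu, new_info = penalized(cand)
            if new_pll >= pll - 1e-12:
                break
            step *= 0.5
        beta = beta + step
        if new_pll - pll < tol and np.abs(score).max() < 1e-5:
            pll, mu, info = new_pll, new_mu, new_info
            converged = True
            break
        pll, mu, info = new_pll, new_mu, new_info
    return LogisticFit(beta, pll, converged, False, "penalized")


def fit_logistic(X: np.ndarray, y: np.ndarray) -> LogisticFit:
    """MLE fit, falling back to Firth on separation or non-convergence."""
    fit = fit_mle(X, y)
    if fit.separated or not fit.converged:
        return fit_firth(X, y)
    return fit
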