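"""Penalized Poisson IRLS core shared by the phenology and GAMM fitters."""

from __future__ import annotations

import numpy as np
from scipy.linalg import cho_factor, cho_solve

_MU_FLOOR = 1e-10


def pirls_poisson(X, y, S, beta0=None, max_iter=100, tol=1e-9):
    """Maximize the S-penalized Poisson log-likelihood (log link).

    Returns ``(beta, eta, mu, XtWX, n_iter)``.  ``S`` is the full (p, p)
    penalty matrix.  Raises on non-convergence with the gradient norm.
    """
    n, p = X.shape
    y = np.asarray(y, dtype=float)
    if beta0 is None:
        beta = np.zeros(p)
        # start from a constant fit if an unpenalized intercept-like column exists
        ybar = max(y.mean(), _MU_FLOOR)
        beta[0] = np.log(ybar) if np.allclose(X[:, 0], 1.0) else 0.0
    else:
        beta = beta0.copy()

    eta = X @ beta
    mu = np.exp(np.clip(eta, -30, 30))
    dev_prev = np.inf
    for it in range(max_iter):
        w = np.maximum(mu, _MU_FLOOR)
        z = eta + (y - mu) / w
        XtWX = (X * w[:, None]).T @ X
        rhs = (X * w[:, None]).T @ z
        A = XtWX + S
        try:
            c = cho_factor(A + 1e-10 * np.eye(p))
            beta_new = cho_solve(c, rhs)
        except np.linalg.LinAlgError:
            beta_new = np.linalg.lstsq(A, rhs, rcond=None)[0]
        # step-halving on the penalized deviance
        step = 1.0
        for _ in range(30):
            b = beta + step * (beta_new - beta)
            eta_b = np.clip(X @ b, -30, 30)
            mu_b = np.exp(eta_b)
            dev = _penalized_deviance(y, mu_b, b, S)
            if dev <= dev_prev + 1e-12 or step < 1e-8:
                break
            step /= 2
        beta, eta, mu = b, eta_b, mu_b
        if abs(dev_prev - dev) < tol * (abs(dev) + 1):
            XtWX = (X * np.maximum(mu, _MU_FLOOR)[:, None]).T @ X
            return beta, eta, mu, XtWX, it + 1
        dev_prev = dev
    grad = X.T @ (y - mu) - S @ beta
    raise RuntimeError(
        f"penalized IRLS did not converge in {max_iter} iterations "
        f"(gradient norm {np.linalg.norm(grad):.3g})"
    )


def _penalized_deviance(y, mu, beta, S):
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(y > 0, y * np.log(y / mu), 0.0)
    return 2.0 * np.sum(term - (y - mu)) + beta @ S @ beta


def poisson_loglik(y, mu):
    """Poisson log-likelihood up to the log(y!) constant."""
    mu = np.maximum(mu, _MU_FLOOR)
    return float(np.sum(y * np.log(mu) - mu))
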