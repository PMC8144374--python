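"""Independent oracles used by the test suite.

Everything here deliberately avoids the package's optimizer and scoring code:
exhaustive grid search over the constrained parameter boxes, and brute-force
tail summation from log-gamma densities.
"""

from __future__ import annotations

import numpy as np
from scipy.special import betaln, gammaln


def _grid_loglik(I, T, alpha_grid, beta_grid):
    """Log-likelihood surface over a (alpha, beta) shape grid."""
    ll = np.zeros_like(alpha_grid, dtype=float)
    for i, t in zip(I, T):
        if t > 0:
            ll += (gammaln(t + 1) - gammaln(i + 1) - gammaln(t - i + 1)
                   + betaln(i + alpha_grid, t - i + beta_grid)
                   - betaln(alpha_grid, beta_grid))
    return ll


def one_group_grid_surface(I, T, omega_max, n_psi=200, n_omega=200):
    """Log-likelihood over a psi x omega grid (psi rows, omega columns)."""
    psis = np.linspace(0.005, 0.995, n_psi)
    omegas = np.linspace(2.01, omega_max + 1.99, n_omega)
    P, O = np.meshgrid(psis, omegas, indexing="ij")
    return _grid_loglik(I, T, O * P, O * (1.0 - P))


def one_group_grid_max(I, T, omega_max, n_psi=200, n_omega=200) -> float:
    return float(one_group_grid_surface(I, T, omega_max, n_psi, n_omega).max())


def two_group_grid_max(I1, T1, I2, T2, omega_max, n_psi=200, n_omega=200) -> float:
    """Best shared-omega two-group log-likelihood on the grid.

    For fixed omega the groups decouple, so the 3-parameter search reduces to
    maximizing each group over psi per omega column and adding.
    """
    s1 = one_group_grid_surface(I1, T1, omega_max, n_psi, n_omega)
    s2 = one_group_grid_surface(I2, T2, omega_max, n_psi, n_omega)
    return float((s1.max(axis=0) + s2.max(axis=0)).max())


def reference_grid_max(I, T, beta_max, n_grid=300) -> float:
    """Best constrained (alpha in (1/beta_max, 1], beta in (1, beta_max]) fit."""
    alphas = np.linspace(1.0 / beta_max + 1e-4, 1.0, n_grid)
    betas = np.linspace(1.0 + 1e-4, beta_max, n_grid)
    A, B = np.meshgrid(alphas, betas, indexing="ij")
    return float(_grid_loglik(I, T, A, B).max())


def tail_prob_bruteforce(i_s: int, t_s: int, alpha: float, beta: float) -> float:
    """P(X >= i_s) by direct summation of exact log-gamma densities."""
    ii = np.arange(i_s, t_s + 1)
    logpdf = (gammaln(t_s + 1) - gammaln(ii + 1) - gammaln(t_s - ii + 1)
              + betaln(ii + alpha, t_s - ii + beta) - betaln(alpha, beta))
    return float(np.exp(logpdf).sum())
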