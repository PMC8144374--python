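"""Beta-binomial log density and log tail probability, computed via log-gamma.

The beta-binomial models an isoform read count I out of total depth T when the
per-sample PSI is itself beta-distributed: the binomial captures sampling
noise at the observed depth, the beta captures biological variation in PSI.
Shapes may be given directly as (alpha, beta) or through the mean/concentration
parameterization psi = alpha/(alpha+beta), omega = alpha+beta.
"""

from __future__ import annotations

import numpy as np
from scipy.special import betaln, gammaln, logsumexp


def betabin_logpdf(i, t, alpha, beta):
    """log P(I = i | T = t) for a BetaBinomial(t, alpha, beta) count.

    Vectorized over all arguments.  ``logpdf(0, 0) = 0`` (empty trial).
    """
    i = np.asarray(i)
    t = np.asarray(t)
    alpha = np.asarray(alpha, dtype=float)
    beta = np.asarray(beta, dtype=float)
    if (i < 0).any() or (i > t).any():
        raise ValueError("require 0 <= i <= t")
    if (alpha <= 0).any() or (beta <= 0).any():
        raise ValueError("alpha and beta must be positive")
    out = (
        gammaln(t + 1)
        - gammaln(i + 1)
        - gammaln(t - i + 1)
        + betaln(i + alpha, t - i + beta)
        - betaln(alpha, beta)
    )
    return out if out.shape else float(out)


def betabin_logsf(i: int, t: int, alpha: float, beta: float) -> float:
    """log P(I >= i), summed exactly in log space over the upper tail."""
    if i <= 0:
        return 0.0
    if i > t:
        raise ValueError("require i <= t")
    support = np.arange(i, t + 1)
    return float(logsumexp(betabin_logpdf(support, t, alpha, beta)))


def betabin_loglik(I, T, psi: float, omega: float) -> float:
    """Sum of log densities under the (psi, omega) parameterization.

    Samples with T = 0 contribute log-density 0 and so drop out naturally.
    """
    I = np.asarray(I)
    T = np.asarray(T)
    covered = T > 0
    if not covered.any():
        return 0.0
    return float(
        np.sum(betabin_logpdf(I[covered], T[covered], omega * psi, omega * (1.0 - psi)))
    )
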