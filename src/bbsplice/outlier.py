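"""Splicing outlier score against a reference panel.

A beta distribution is fitted to the minor-isoform fraction across a set of
reference samples, constrained to be strictly decreasing on [0, 1]:

    alpha_R in (1/beta_max, 1],  beta_R in (1, beta_max]

via the logistic reparameterization

    alpha_R = (1 - 1/beta_max) / (1 + e^a) + 1/beta_max
    beta_R  = (beta_max - 1) / (1 + e^b) + 1

If the reference contains zero minor-isoform reads the fit degenerates and the
closed form alpha_R = 1, beta_R = min(beta_max, sum T_n) is used instead.

A test sample with minor count I_s out of T_s is scored by the upper-tail
probability of its minor count under the fitted beta-binomial:

    score = -log10 P(X >= I_s),   X ~ BetaBinomial(T_s, alpha_R, beta_R)

The score is 0 when I_s = 0 and grows as the minor isoform exceeds what the
reference distribution supports.  Note the score uses base-10 logarithms, so
a score of 10 corresponds to a tail probability of 1e-10.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .events import EventCountTable, EventValidationError, make_event_jid
from .likelihood import betabin_logpdf, betabin_logsf

DEFAULT_BETA_MAX = 80.0
DEFAULT_SCORE_THRESHOLD = 10.0

_LN10 = float(np.log(10.0))


def alpha_from_a(a: float, beta_max: float) -> float:
    lo = 1.0 / beta_max
    with np.errstate(over="ignore"):
        return float(np.clip((1.0 - lo) / (1.0 + np.exp(a)) + lo, lo + 1e-12, 1.0))


def beta_from_b(b: float, beta_max: float) -> float:
    with np.errstate(over="ignore"):
        return float(np.clip((beta_max - 1.0) / (1.0 + np.exp(b)) + 1.0, 1.0 + 1e-12, beta_max))


def a_from_alpha(alpha: float, beta_max: float) -> float:
    lo = 1.0 / beta_max
    alpha = float(np.clip(alpha, lo + 1e-6, 1.0 - 1e-6))
    return float(np.log((1.0 - lo) / (alpha - lo) - 1.0))


def b_from_beta(beta: float, beta_max: float) -> float:
    beta = float(np.clip(beta, 1.0 + 1e-6, beta_max - 1e-6))
    return float(np.log((beta_max - 1.0) / (beta - 1.0) - 1.0))


@dataclass
class ReferenceFit:
    alpha: float
    beta: float
    beta_max: float
    minor_isoform: int  # 1 or 2
    fit_status: str     # optimized | zero_minor | insufficient
    n_reference: int
    loglik: float = float("nan")


def orient_minor(iso1_counts, iso2_counts) -> int:
    """Isoform with mean reference PSI < 0.5 over covered samples; ties -> 1."""
    iso1 = np.asarray(iso1_counts, dtype=float)
    iso2 = np.asarray(iso2_counts, dtype=float)
    totals = iso1 + iso2
    covered = totals > 0
    if not covered.any():
        raise EventValidationError("no covered reference samples")
    mean_psi1 = float(np.mean(iso1[covered] / totals[covered]))
    return 1 if mean_psi1 <= 0.5 else 2


def fit_reference(I_minor, T, beta_max: float = DEFAULT_BETA_MAX,
                  minor_isoform: int = 1) -> ReferenceFit:
    """Constrained maximum-likelihood beta fit to minor-isoform reference counts."""
    if beta_max <= 1:
        raise ValueError("beta_max must exceed 1")
    I = np.asarray(I_minor, dtype=np.int64)
    T = np.asarray(T, dtype=np.int64)
    covered = T > 0
    n_ref = int(covered.sum())
    if n_ref == 0:
        return ReferenceFit(np.nan, np.nan, beta_max, minor_isoform, "insufficient", 0)
    Ic, Tc = I[covered], T[covered]
    if Ic.sum() == 0:
        beta = float(min(beta_max, float(Tc.sum())))
        ll = float(np.sum(betabin_logpdf(Ic, Tc, 1.0, beta)))
        return ReferenceFit(1.0, beta, beta_max, minor_isoform, "zero_minor", n_ref, ll)

    def nll(x):
        return -float(np.sum(betabin_logpdf(
            Ic, Tc, alpha_from_a(x[0], beta_max), beta_from_b(x[1], beta_max))))

    mean_minor_psi = float(np.mean(Ic / Tc))
    a0 = a_from_alpha(min(0.9, mean_minor_psi + 0.05), beta_max)
    b0 = b_from_beta(beta_max / 2.0, beta_max)
    best_x, best_f = None, np.inf
    for x0 in [(a0, b0), (a0, b_from_beta(5.0, beta_max)), (0.0, 0.0)]:
        f0 = nll(np.asarray(x0, dtype=float))
        if f0 < best_f:
            best_x, best_f = np.asarray(x0, dtype=float), f0
        res = minimize(nll, x0, method="Nelder-Mead",
                       options={"maxiter": 500, "fatol": 1e-8, "xatol": 1e-6})
        if res.fun < best_f:
            best_x, best_f = res.x, res.fun
        if not res.success:
            try:
                res2 = minimize(nll, x0, method="BFGS", options={"maxiter": 500})
                if np.isfinite(res2.fun) and res2.fun < best_f:
                    best_x, best_f = res2.x, res2.fun
            except (ValueError, FloatingPointError):
                pass
    return ReferenceFit(
        alpha=alpha_from_a(best_x[0], beta_max),
        beta=beta_from_b(best_x[1], beta_max),
        beta_max=beta_max, minor_isoform=minor_isoform,
        fit_status="optimized", n_reference=n_ref, loglik=-best_f,
    )


def outlier_score(i_s: int, t_s: int, fit: ReferenceFit) -> float:
    """-log10 upper-tail probability of the minor-isoform count; NaN at T=0."""
    if t_s == 0:
        return float("nan")
    if i_s < 0 or i_s > t_s:
        raise ValueError("require 0 <= i_s <= t_s")
    if i_s == 0:
        return 0.0
    return -betabin_logsf(i_s, t_s, fit.alpha, fit.beta) / _LN10


def outlier_scan(table: EventCountTable, reference_samples, test_samples,
                 beta_max: float = DEFAULT_BETA_MAX,
                 threshold: float = DEFAULT_SCORE_THRESHOLD) -> pd.DataFrame:
    """Per-event reference fit and per-test-sample outlier scores.

    Orientation (which isoform is 'minor') is decided per event on the
    reference samples only, then applied unchanged to the test samples.
    """
    ref_idx = table.sample_index(reference_samples)
    test_idx = table.sample_index(test_samples)
    test_names = list(test_samples)
    rows = []
    for k, event in enumerate(table.events):
        jid = make_event_jid(event)
        i1r = table.iso1_counts[k, ref_idx]
        i2r = table.iso2_counts[k, ref_idx]
        Tr = i1r + i2r
        base = dict(event_id=event.event_id, event_jid=jid, gene=event.gene_id,
                    event_type=event.event_type)
        if not (Tr > 0).any():
            for s in test_names:
                rows.append({**base, "sample": s, "minor_isoform": 0,
                             "minor_count": np.nan, "total": np.nan,
                             "alpha_R": np.nan, "beta_R": np.nan, "score": np.nan,
                             "passes_threshold": False, "fit_status": "insufficient"})
            continue
        minor = orient_minor(i1r, i2r)
        I_minor_ref = i1r if minor == 1 else i2r
        fit = fit_reference(I_minor_ref, Tr, beta_max, minor_isoform=minor)
        minor_counts = table.iso1_counts if minor == 1 else table.iso2_counts
        for s, j in zip(test_names, test_idx):
            i_s = int(minor_counts[k, j])
            t_s = int(table.totals[k, j])
            score = outlier_score(i_s, t_s, fit) if fit.fit_status != "insufficient" else np.nan
            rows.append({**base, "sample": s, "minor_isoform": minor,
                         "minor_count": i_s, "total": t_s,
                         "alpha_R": fit.alpha, "beta_R": fit.beta, "score": score,
                         "passes_threshold": bool(np.isfinite(score) and score > threshold),
                         "fit_status": fit.fit_status})
    return pd.DataFrame(rows)


def combine_scores_min(scores_a: pd.DataFrame, scores_b: pd.DataFrame) -> pd.DataFrame:
    """Element-wise minimum of two score matrices (event_jid x sample).

    A missing value in either input is conservative and propagates as missing:
    an event only passes combined thresholding when both analyses score it.
    """
    if not scores_a.index.equals(scores_b.index) or not list(scores_a.columns) == list(scores_b.columns):
        a_sorted = scores_a.sort_index().sort_index(axis=1)
        b_sorted = scores_b.sort_index().sort_index(axis=1)
        if not a_sorted.index.equals(b_sorted.index) or list(a_sorted.columns) != list(b_sorted.columns):
            raise EventValidationError("score matrices have mismatched event/sample indexes")
        scores_a, scores_b = a_sorted, b_sorted
    return pd.DataFrame(np.minimum(scores_a.to_numpy(float), scores_b.to_numpy(float)),
                        index=scores_a.index, columns=scores_a.columns)


def scores_to_matrix(scan: pd.DataFrame) -> pd.DataFrame:
    """Pivot the long outlier_scan output to an event_jid x sample score matrix."""
    return scan.pivot(index="event_jid", columns="sample", values="score")
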