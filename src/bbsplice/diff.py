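"""Two-group beta-binomial differential splicing test.

For each event, isoform-1 read counts I_n out of totals T_n are modeled as
beta-binomial.  The one-group model fits a single expected PSI and
concentration (psi_A, omega_A) to all samples; the two-group model fits
separate means (psi_1, psi_2) with a shared concentration omega_G.  The test
statistic is the log-likelihood improvement of the two-group model:

    lr = loglik_two_group - loglik_one_group  >= 0

Large lr indicates the two groups have different underlying PSI distributions.
Optimization runs in unconstrained coordinates (a, b) through logistic maps

    omega = omega_max / (1 + e^a) + 2        (2 < omega < omega_max + 2)
    psi   = 1 / (1 + e^b)                    (0 < psi < 1)

using Nelder-Mead with a BFGS fallback, started from method-of-moments PSI.
The two-group fit additionally starts from the one-group optimum, which
guarantees the nesting inequality up to solver tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .events import EventCountTable, EventValidationError, make_event_jid
from .likelihood import betabin_loglik

DEFAULT_OMEGA_MAX = 200.0
DEFAULT_LR_THRESHOLD = 8.0

_PSI_EPS = 1e-12
_OMEGA_EPS = 1e-9


def omega_from_a(a: float, omega_max: float) -> float:
    with np.errstate(over="ignore"):
        return float(np.clip(omega_max / (1.0 + np.exp(a)) + 2.0,
                             2.0 + _OMEGA_EPS, omega_max + 2.0 - _OMEGA_EPS))


def psi_from_b(b: float) -> float:
    with np.errstate(over="ignore"):
        return float(np.clip(1.0 / (1.0 + np.exp(b)), _PSI_EPS, 1.0 - _PSI_EPS))


def a_from_omega(omega: float, omega_max: float) -> float:
    omega = float(np.clip(omega, 2.0 + 1e-6, omega_max + 2.0 - 1e-6))
    return float(np.log(omega_max / (omega - 2.0) - 1.0)) if omega < omega_max + 2.0 - 1e-6 else -30.0


def b_from_psi(psi: float) -> float:
    psi = float(np.clip(psi, 1e-6, 1.0 - 1e-6))
    return float(np.log(1.0 / psi - 1.0))


@dataclass
class DiffModelParams:
    """Fitted one-group parameters on both natural and optimizer scales."""

    psi: float
    omega: float
    a: float
    b: float
    omega_max: float


@dataclass
class OneGroupFit:
    params: DiffModelParams | None
    loglik: float
    n_used: int
    status: str  # optimized | insufficient


@dataclass
class TwoGroupFit:
    psi1: float
    psi2: float
    omega: float
    loglik: float
    n_used1: int
    n_used2: int
    status: str


@dataclass
class DiffResult:
    event_id: str
    event_jid: str
    gene_id: str
    event_type: str
    lr: float
    psi_group1: float
    psi_group2: float
    psi_one_group: float
    omega: float
    loglik_one_group: float
    loglik_two_group: float
    group_increased_alt: str
    n_used_group1: int
    n_used_group2: int
    fit_status: str


def _minimize(objective, starts, maxiter=500, tol=1e-8):
    """Nelder-Mead from several starts, BFGS fallback; return best point found."""
    best_x, best_f = None, np.inf
    for x0 in starts:
        f0 = objective(np.asarray(x0, dtype=float))
        if f0 < best_f:
            best_x, best_f = np.asarray(x0, dtype=float), f0
        res = minimize(objective, x0, method="Nelder-Mead",
                       options={"maxiter": maxiter, "fatol": tol, "xatol": 1e-6})
        if res.fun < best_f:
            best_x, best_f = res.x, res.fun
        if not res.success:
            try:
                res2 = minimize(objective, x0, method="BFGS",
                                options={"maxiter": maxiter})
                if np.isfinite(res2.fun) and res2.fun < best_f:
                    best_x, best_f = res2.x, res2.fun
            except (ValueError, FloatingPointError):
                pass
    return best_x, best_f


def _moment_psi(I: np.ndarray, T: np.ndarray) -> float:
    # lightly smoothed pooled estimate; keeps the start off the boundary
    return float((I.sum() + 0.5) / (T.sum() + 1.0))


def fit_one_group(I, T, omega_max: float = DEFAULT_OMEGA_MAX) -> OneGroupFit:
    """Maximum-likelihood (psi, omega) for one group of samples."""
    I = np.asarray(I, dtype=np.int64)
    T = np.asarray(T, dtype=np.int64)
    if I.shape != T.shape:
        raise ValueError("I and T must have the same length")
    covered = T > 0
    n_used = int(covered.sum())
    if n_used == 0:
        return OneGroupFit(None, float("nan"), 0, "insufficient")
    Ic, Tc = I[covered], T[covered]

    def nll(x):
        return -betabin_loglik(Ic, Tc, psi_from_b(x[1]), omega_from_a(x[0], omega_max))

    b0 = b_from_psi(_moment_psi(Ic, Tc))
    starts = [(0.0, b0), (2.0, b0), (-2.0, b0)]
    x, f = _minimize(nll, starts)
    params = DiffModelParams(
        psi=psi_from_b(x[1]), omega=omega_from_a(x[0], omega_max),
        a=float(x[0]), b=float(x[1]), omega_max=omega_max,
    )
    return OneGroupFit(params, -f, n_used, "optimized")


def fit_two_group(I1, T1, I2, T2, omega_max: float = DEFAULT_OMEGA_MAX,
                  one_group_start: DiffModelParams | None = None) -> TwoGroupFit:
    """Maximum-likelihood (psi1, psi2, shared omega) across two groups."""
    I1 = np.asarray(I1, dtype=np.int64); T1 = np.asarray(T1, dtype=np.int64)
    I2 = np.asarray(I2, dtype=np.int64); T2 = np.asarray(T2, dtype=np.int64)
    c1, c2 = T1 > 0, T2 > 0
    n1, n2 = int(c1.sum()), int(c2.sum())
    if n1 == 0 or n2 == 0:
        return TwoGroupFit(*(float("nan"),) * 4, n1, n2, "insufficient")
    I1c, T1c, I2c, T2c = I1[c1], T1[c1], I2[c2], T2[c2]

    def nll(x):
        omega = omega_from_a(x[0], omega_max)
        return -(betabin_loglik(I1c, T1c, psi_from_b(x[1]), omega)
                 + betabin_loglik(I2c, T2c, psi_from_b(x[2]), omega))

    b01 = b_from_psi(_moment_psi(I1c, T1c))
    b02 = b_from_psi(_moment_psi(I2c, T2c))
    starts = [(0.0, b01, b02), (2.0, b01, b02), (-2.0, b01, b02)]
    if one_group_start is not None:
        starts.append((one_group_start.a, one_group_start.b, one_group_start.b))
    x, f = _minimize(nll, starts)
    return TwoGroupFit(
        psi1=psi_from_b(x[1]), psi2=psi_from_b(x[2]),
        omega=omega_from_a(x[0], omega_max), loglik=-f,
        n_used1=n1, n_used2=n2, status="optimized",
    )


def _split_groups(table: EventCountTable, groups) -> tuple[str, str, np.ndarray, np.ndarray]:
    labels = {}
    for sample, label in groups.items():
        labels.setdefault(str(label), []).append(sample)
    if len(labels) != 2:
        raise EventValidationError(f"need exactly two group labels, got {sorted(labels)}")
    order = {s: i for i, s in enumerate(table.samples)}
    for sample in groups:
        if sample not in order:
            raise EventValidationError(f"unknown sample {sample!r} in group assignment")
    # group 1 = label whose first sample appears first in the table
    lab_sorted = sorted(labels, key=lambda lab: min(order[s] for s in labels[lab]))
    g1, g2 = lab_sorted
    return g1, g2, table.sample_index(labels[g1]), table.sample_index(labels[g2])


def diff_test(table: EventCountTable, groups, omega_max: float = DEFAULT_OMEGA_MAX,
              lr_threshold: float = DEFAULT_LR_THRESHOLD,
              min_samples_per_group: int = 2) -> pd.DataFrame:
    """Differential splicing test for every event in the table.

    ``groups`` maps sample id -> one of exactly two group labels.  Events with
    fewer than ``min_samples_per_group`` covered samples in either group are
    flagged ``insufficient`` rather than scored.  Results are sorted by lr
    descending with a stable tie-break on event_id.
    """
    g1, g2, idx1, idx2 = _split_groups(table, groups)
    rows = []
    for k, event in enumerate(table.events):
        I1, T1 = table.iso1_counts[k, idx1], table.totals[k, idx1]
        I2, T2 = table.iso1_counts[k, idx2], table.totals[k, idx2]
        n1, n2 = int((T1 > 0).sum()), int((T2 > 0).sum())
        base = dict(
            event_id=event.event_id, event_jid=make_event_jid(event),
            gene=event.gene_id, event_type=event.event_type,
            n_used_group1=n1, n_used_group2=n2,
            group1=g1, group2=g2,
        )
        if n1 < min_samples_per_group or n2 < min_samples_per_group:
            rows.append({**base, "lr": np.nan, "psi_group1": np.nan, "psi_group2": np.nan,
                         "psi_one_group": np.nan, "omega": np.nan,
                         "loglik_one_group": np.nan, "loglik_two_group": np.nan,
                         "group_increased_alt": "", "passes_threshold": False,
                         "fit_status": "insufficient"})
            continue
        one = fit_one_group(np.concatenate([I1, I2]), np.concatenate([T1, T2]), omega_max)
        two = fit_two_group(I1, T1, I2, T2, omega_max, one_group_start=one.params)
        lr = two.loglik - one.loglik
        # alternative isoform (iso2) is increased where iso1 PSI is lower
        inc_alt = g1 if two.psi1 < two.psi2 else g2
        rows.append({**base, "lr": lr, "psi_group1": two.psi1, "psi_group2": two.psi2,
                     "psi_one_group": one.params.psi, "omega": two.omega,
                     "loglik_one_group": one.loglik, "loglik_two_group": two.loglik,
                     "group_increased_alt": inc_alt,
                     "passes_threshold": bool(lr > lr_threshold),
                     "fit_status": "optimized"})
    df = pd.DataFrame(rows)
    if len(df):
        df = df.sort_values(["lr", "event_id"], ascending=[False, True],
                            kind="mergesort", na_position="last").reset_index(drop=True)
    return df
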