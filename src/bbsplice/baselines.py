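"""Comparator statistics: Welch t-test on PSI and MAD / IQR outlier scores.

These are the simple PSI-distribution methods the beta-binomial tests are
benchmarked against.  All operate on PSI values and support depth masking
(PSI treated as missing below a depth cutoff, conventionally 10).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .events import EventCountTable, make_event_jid

DENOM_FLOOR = 0.01


def welch_t_psi(psi_group1, psi_group2) -> tuple[float, str]:
    """Two-sided unequal-variance t-test p-value on PSI values.

    Returns (p_value, status).  status is ``insufficient`` with p = NaN when a
    group has fewer than two non-missing values, ``degenerate`` when both
    within-group variances are zero (p = 1 if the means agree, else p = 0 so
    that benchmark sweeps complete), and ``ok`` otherwise.
    """
    x1 = np.asarray(psi_group1, dtype=float)
    x2 = np.asarray(psi_group2, dtype=float)
    x1 = x1[np.isfinite(x1)]
    x2 = x2[np.isfinite(x2)]
    if len(x1) < 2 or len(x2) < 2:
        return float("nan"), "insufficient"
    v1, v2 = x1.var(ddof=1), x2.var(ddof=1)
    if v1 == 0.0 and v2 == 0.0:
        return (1.0, "degenerate") if x1.mean() == x2.mean() else (0.0, "degenerate")
    res = stats.ttest_ind(x1, x2, equal_var=False)
    return float(res.pvalue), "ok"


def mad_score(x_s: float, x_R) -> float:
    """Signed deviation of x_s from the reference median, in MAD units.

    (x_s - median(x_R)) / max(median(|x_R - median(x_R)|), 0.01).
    """
    xr = np.asarray(x_R, dtype=float)
    xr = xr[np.isfinite(xr)]
    if len(xr) == 0 or not np.isfinite(x_s):
        return float("nan")
    med = float(np.median(xr))
    mad = float(np.median(np.abs(xr - med)))
    return (x_s - med) / max(mad, DENOM_FLOOR)


def iqr_score(x_s: float, x_R) -> float:
    """Distance of x_s outside the reference interquartile interval, in IQR units.

    Zero inside [Q25, Q75]; otherwise the gap to the nearest quartile divided
    by max(Q75 - Q25, 0.01).  Quartiles use linear interpolation between order
    statistics.  Always non-negative.
    """
    xr = np.asarray(x_R, dtype=float)
    xr = xr[np.isfinite(xr)]
    if len(xr) == 0 or not np.isfinite(x_s):
        return float("nan")
    q25, q75 = np.percentile(xr, [25.0, 75.0])
    denom = max(float(q75 - q25), DENOM_FLOOR)
    if x_s < q25:
        return float(q25 - x_s) / denom
    if x_s > q75:
        return float(x_s - q75) / denom
    return 0.0


def ttest_scan(table: EventCountTable, groups, min_depth: int = 0) -> pd.DataFrame:
    """Per-event Welch t-test on PSI between two groups, with depth masking."""
    from .diff import _split_groups  # shared group bookkeeping

    g1, g2, idx1, idx2 = _split_groups(table, groups)
    psi = table.psi(min_depth=min_depth)
    rows = []
    for k, event in enumerate(table.events):
        x1, x2 = psi[k, idx1], psi[k, idx2]
        p, status = welch_t_psi(x1, x2)
        rows.append(dict(
            event_id=event.event_id, event_jid=make_event_jid(event),
            gene=event.gene_id, event_type=event.event_type,
            method="ttest", masked=min_depth > 0, value=p,
            n_used_group1=int(np.isfinite(x1).sum()),
            n_used_group2=int(np.isfinite(x2).sum()),
            fit_status=status,
        ))
    return pd.DataFrame(rows)


def baseline_outlier_scan(table: EventCountTable, reference_samples, test_samples,
                          method: str = "mad", min_depth: int = 0,
                          absolute: bool = False) -> pd.DataFrame:
    """MAD or IQR outlier score per event x test sample against a reference panel.

    ``absolute`` reports |MAD| instead of the signed value (no effect on IQR,
    which is non-negative by construction).
    """
    if method not in ("mad", "iqr"):
        raise ValueError(f"unknown baseline method {method!r}")
    ref_idx = table.sample_index(reference_samples)
    test_idx = table.sample_index(test_samples)
    psi = table.psi(min_depth=min_depth)
    rows = []
    for k, event in enumerate(table.events):
        x_ref = psi[k, ref_idx]
        for s, j in zip(test_samples, test_idx):
            x_s = psi[k, j]
            if method == "mad":
                val = mad_score(x_s, x_ref)
                if absolute and np.isfinite(val):
                    val = abs(val)
            else:
                val = iqr_score(x_s, x_ref)
            rows.append(dict(
                event_id=event.event_id, event_jid=make_event_jid(event),
                gene=event.gene_id, event_type=event.event_type,
                sample=s, method=method, masked=min_depth > 0, value=val,
                n_used=int(np.isfinite(x_ref).sum()),
            ))
    return pd.DataFrame(rows)
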