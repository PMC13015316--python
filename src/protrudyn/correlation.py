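"""Offset correlations, bootstrap confidence intervals, zero-centered
correlations, and threshold-persistence population curves.

The lagged Pearson correlation of two single-cell time series (e.g. total
front protrusion activity vs. total rear retraction activity) is estimated
on the offset-aligned overlap; a percentile bootstrap gives the 95%
confidence interval at every lag, and the lag of the peak correlation is
accepted as a characteristic time offset only when the lower CI bound at
the peak exceeds 0.2.  A positive peak offset means the second series lags
the first.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


def _aligned(x: np.ndarray, y: np.ndarray, lag: int):
    """Overlap of x(t) and y(t+lag) for an integer frame lag."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if lag >= 0:
        a, b = x[: len(x) - lag or None], y[lag:]
    else:
        a, b = x[-lag:], y[: len(y) + lag]
    m = min(len(a), len(b))
    return a[:m], b[:m]


def offset_pearson(x: np.ndarray, y: np.ndarray, lag: int) -> float:
    """Pearson correlation of x(t) with y(t+lag) on the aligned overlap.

    Returns NaN (flagged undefined) when fewer than 3 samples overlap or
    either series has zero variance on the overlap.
    """
    a, b = _aligned(x, y, lag)
    if len(a) < 3 or np.std(a) == 0 or np.std(b) == 0:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


@dataclass
class OffsetCorrelation:
    lags: np.ndarray            # s
    corr: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    peak_offset: float          # s
    peak_corr: float
    peak_valid: bool


def bootstrap_peak_offset(
    x: np.ndarray,
    y: np.ndarray,
    max_lag: int,
    frame_interval: float = 1.0,
    n_boot: int = 1000,
    seed: int = 0,
    block_length: int | None = None,
    validity_threshold: float = 0.2,
) -> OffsetCorrelation:
    """Lagged correlation with percentile bootstrap CIs and peak validity.

    Resampling draws time points of the aligned overlap with replacement
    (``block_length`` switches to a stationary block bootstrap for
    autocorrelated series).  The peak offset is the lag maximizing the
    plug-in correlation; it is valid when the lower 95% CI bound at the
    peak exceeds ``validity_threshold``.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100 for a stable percentile CI")
    rng = np.random.default_rng(seed)
    lags = np.arange(-max_lag, max_lag + 1)
    corr = np.array([offset_pearson(x, y, int(s)) for s in lags])
    lo = np.full(len(lags), np.nan)
    hi = np.full(len(lags), np.nan)
    for i, s in enumerate(lags):
        a, b = _aligned(x, y, int(s))
        m = len(a)
        if m < 3 or not np.isfinite(corr[i]):
            continue
        if block_length and block_length > 1:
            n_blocks = int(np.ceil(m / block_length))
            starts = rng.integers(0, m, size=(n_boot, n_blocks))
            idx = (starts[:, :, None] + np.arange(block_length)) % m
            idx = idx.reshape(n_boot, -1)[:, :m]
        else:
            idx = rng.integers(0, m, size=(n_boot, m))
        ra, rb = a[idx], b[idx]
        ra = ra - ra.mean(axis=1, keepdims=True)
        rb = rb - rb.mean(axis=1, keepdims=True)
        denom = np.sqrt((ra * ra).sum(axis=1) * (rb * rb).sum(axis=1))
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (ra * rb).sum(axis=1) / denom
        r = r[np.isfinite(r)]
        if len(r):
            lo[i], hi[i] = np.percentile(r, [2.5, 97.5])
    if np.all(~np.isfinite(corr)):
        return OffsetCorrelation(lags * frame_interval, corr, lo, hi, np.nan, np.nan, False)
    peak = int(np.nanargmax(corr))
    valid = bool(np.isfinite(lo[peak]) and lo[peak] > validity_threshold)
    return OffsetCorrelation(
        lags=lags * frame_interval,
        corr=corr,
        ci_lower=lo,
        ci_upper=hi,
        peak_offset=float(lags[peak] * frame_interval),
        peak_corr=float(corr[peak]),
        peak_valid=valid,
    )


def front_rear_activity(area_change: np.ndarray, front_idx: np.ndarray, rear_idx: np.ndarray):
    """Per-frame magnitudes of total front protrusion and rear retraction.

    Front activity sums the positive local area changes over the front
    points; rear activity sums the magnitudes of the negative local area
    changes over the rear points.
    """
    a = np.asarray(area_change, float)
    front = np.clip(a[..., front_idx], 0, None).sum(axis=-1)
    rear = np.clip(-a[..., rear_idx], 0, None).sum(axis=-1)
    return front, rear


def front_rear_direction_correlation(
    n_front: list[np.ndarray],
    n_rear: list[np.ndarray],
    max_lag: int,
    frame_interval: float = 1.0,
) -> pd.DataFrame:
    """Population-averaged ⟨n_front(t)·n_rear(t+Δt)⟩ at positive and
    negative lags; undefined-direction frames are skipped."""
    rows = []
    for lag in range(-max_lag, max_lag + 1):
        dots = []
        for f, r in zip(n_front, n_rear):
            if lag >= 0:
                a, b = f[: len(f) - lag or None], r[lag:]
            else:
                a, b = f[-lag:], r[: len(r) + lag]
            m = min(len(a), len(b))
            v = np.einsum("ij,ij->i", a[:m], b[:m])
            dots.append(v[np.isfinite(v)])
        allv = np.concatenate(dots) if dots else np.array([])
        if len(allv):
            rows.append({"dt": lag * frame_interval, "corr": float(allv.mean()),
                         "n_pairs": int(len(allv))})
    return pd.DataFrame(rows)


def zero_centered_correlation(x: np.ndarray, y: np.ndarray) -> float:
    """Correlation with x centralized at 0 instead of its mean.

    Corr′ = ⟨x·(y−⟨y⟩)⟩ / √(⟨x·x⟩·Cov(y,y)).  Used for local curvature or
    membrane motion (x) against the local cortical level (y), so that the
    sign reflects association with positive vs. negative x, not deviation
    from mean x.  NaN where a denominator vanishes.
    """
    x = np.asarray(x, float).ravel()
    y = np.asarray(y, float).ravel()
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 2:
        return np.nan
    if np.mean(x * x) == 0:
        return 0.0          # x ≡ 0 forces Cov′ = 0
    cov_prime = np.mean(x * (y - y.mean()))
    denom = np.sqrt(np.mean(x * x) * np.mean((y - y.mean()) ** 2))
    if denom == 0:
        return np.nan       # constant y: Cov(y, y) = 0, undefined
    return float(cov_prime / denom)


# ---------------------------------------------------------------------------
# threshold-persistence representation

def persistence_fraction(x: np.ndarray, xthr: float) -> float:
    """Time fraction f of a single-cell series maintained above xthr."""
    x = np.asarray(x, float)
    x = x[np.isfinite(x)]
    if len(x) == 0:
        return np.nan
    return float(np.mean(x > xthr))


@dataclass
class PersistenceCurve:
    name: str
    xthr: np.ndarray
    f_mean: np.ndarray          # mean cell fraction F over experiments
    f_sem: np.ndarray
    anova_p: np.ndarray         # per-threshold one-way ANOVA across populations
    tthr: float


def population_persistence(
    cells: pd.DataFrame,
    xthr_grid: np.ndarray,
    tthr: float = 0.5,
    name: str = "x",
) -> PersistenceCurve:
    """Population persistence curve F̄(xthr, tthr) with per-threshold ANOVA.

    ``cells`` needs columns ``cell_id``, ``experiment``, ``population`` and
    ``value`` (the per-frame series values, long form).  For each
    experiment, F is the fraction of its cells whose time fraction f above
    xthr exceeds tthr; the curve is the mean ± SEM of F over experiments,
    and the p-value at each xthr is a one-way ANOVA of the per-experiment F
    across populations (NaN when only one population or one experiment).
    """
    xthr_grid = np.asarray(xthr_grid, float)
    groups = cells.groupby(["population", "experiment", "cell_id"])["value"]
    per_cell = {key: g.to_numpy() for key, g in groups}
    f_mean = np.empty(len(xthr_grid))
    f_sem = np.empty(len(xthr_grid))
    p_vals = np.full(len(xthr_grid), np.nan)
    populations = sorted({k[0] for k in per_cell})
    for i, thr in enumerate(xthr_grid):
        per_exp_f: dict[tuple, list[float]] = {}
        for (pop, exp, _), series in per_cell.items():
            f = persistence_fraction(series, thr)
            per_exp_f.setdefault((pop, exp), []).append(float(f > tthr))
        big_f = {k: np.mean(v) for k, v in per_exp_f.items()}
        all_f = np.array(list(big_f.values()))
        f_mean[i] = all_f.mean()
        f_sem[i] = all_f.std(ddof=1) / np.sqrt(len(all_f)) if len(all_f) > 1 else np.nan
        if len(populations) > 1:
            samples = [
                np.array([v for (p, _), v in big_f.items() if p == pop])
                for pop in populations
            ]
            if all(len(s) > 1 for s in samples):
                p_vals[i] = stats.f_oneway(*samples).pvalue
    return PersistenceCurve(
        name=name, xthr=xthr_grid, f_mean=f_mean, f_sem=f_sem, anova_p=p_vals, tthr=tthr
    )
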