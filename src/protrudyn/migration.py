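"""Cell-scale motility measures.

Path length, average and instantaneous speed, tortuosity, the two-frame
smoothed migration direction, deviation angles, and the population
direction autocorrelation Corr(Δt) = ⟨n(t)·n(t+Δt)⟩.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class MigrationSummary:
    path_length: float          # l, µm
    elapsed: float              # ΔT, s
    displacement: np.ndarray    # s, µm vector
    average_speed: float        # l/ΔT, µm/s
    instant_speed: np.ndarray   # per step, µm/s
    tortuosity: float           # l/|s|, ≥ 1; NaN when |s| = 0
    tortuosity_defined: bool


def path_metrics(centroid_path: np.ndarray, frame_interval: float) -> MigrationSummary:
    """Speeds and tortuosity of a centroid path (n ≥ 2 positions)."""
    path = np.asarray(centroid_path, float)
    if len(path) < 2:
        raise ValueError("need at least two frames")
    steps = np.linalg.norm(np.diff(path, axis=0), axis=1)
    l = float(steps.sum())
    elapsed = (len(path) - 1) * frame_interval
    disp = path[-1] - path[0]
    disp_len = float(np.linalg.norm(disp))
    defined = disp_len > 0
    return MigrationSummary(
        path_length=l,
        elapsed=elapsed,
        displacement=disp,
        average_speed=l / elapsed,
        instant_speed=steps / frame_interval,
        tortuosity=l / disp_len if defined else np.nan,
        tortuosity_defined=defined,
    )


def migration_direction(centroid_path: np.ndarray) -> np.ndarray:
    """Unit migration direction n(t) = unit(c(t+2) − c(t)) per frame.

    The two-frame window smooths subcellular fluctuations out of the
    heading estimate.  Undefined (NaN) at the last two frames and wherever
    the two-frame displacement is zero.
    """
    path = np.asarray(centroid_path, float)
    n = np.full_like(path, np.nan)
    disp = path[2:] - path[:-2]
    norms = np.linalg.norm(disp, axis=1)
    ok = norms > 0
    n[:-2][ok] = disp[ok] / norms[ok, None]
    return n


def deviation_angles(directions: np.ndarray) -> np.ndarray:
    """Angle between n(t) and n(t+1) in [0, π]; NaN where either is undefined."""
    d = np.asarray(directions, float)
    dots = np.einsum("ij,ij->i", d[:-1], d[1:])
    out = np.full(len(d), np.nan)
    out[:-1] = np.arccos(np.clip(dots, -1.0, 1.0))
    return out


def direction_autocorrelation(
    direction_sets: list[np.ndarray],
    max_lag: int | None = None,
    frame_interval: float = 1.0,
) -> pd.DataFrame:
    """Population direction autocorrelation Corr(Δt) = ⟨n(t)·n(t+Δt)⟩.

    Averages the dot product over every valid (t, t+Δt) pair in every
    track.  The lag grid runs in integer frame multiples up to ``max_lag``
    (default: half the longest track).  Lags with no valid pairs are
    omitted.
    """
    lengths = [len(d) for d in direction_sets]
    if max_lag is None:
        max_lag = max(lengths) // 2
    rows = []
    for lag in range(max_lag + 1):
        dots = []
        for d in direction_sets:
            if len(d) <= lag:
                continue
            a, b = d[: len(d) - lag], d[lag:]
            v = np.einsum("ij,ij->i", a, b)
            dots.append(v[np.isfinite(v)])
        if dots:
            allv = np.concatenate(dots)
            if len(allv):
                rows.append({
                    "dt": lag * frame_interval,
                    "corr": float(allv.mean()),
                    "n_pairs": int(len(allv)),
                })
    return pd.DataFrame(rows)


def fit_persistence(autocorr: pd.DataFrame, frame_interval: float) -> float:
    """Per-step heading correlation ρ from the exponential decay of
    Corr(Δt) ≈ ρ^(Δt/frame_interval), by log-linear least squares over the
    positive-correlation lags."""
    df = autocorr[(autocorr["dt"] > 0) & (autocorr["corr"] > 0)]
    if df.empty:
        return 0.0
    steps = df["dt"].to_numpy() / frame_interval
    slope = np.sum(steps * np.log(df["corr"].to_numpy())) / np.sum(steps * steps)
    return float(np.exp(slope))
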