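"""Globally aligned protrusion windows, directional parameters, PCA-based
composite directionality index (CDI), and protrusion-state temporal
organization.

Protrusion-resolved measurements are sliced from the cell's global frame
series: a protrusion starting at table frame ``Frame`` (1-based) occupies
the half-open window ``[Frame−1, Frame−1 + round(lifetime/interval))`` in
0-based coordinates, with expansion / stabilization / retraction phase
frame counts applied sequentially inside the window.  Directional
parameters of each window's centroid subpath are z-scored, reduced with an
SVD PCA (PC1 sign anchored to net displacement), summarized by the CDI
(row mean of the z-scores), and median-split into high- and
low-directionality states, whose ordering along each trajectory yields
first-order transition probabilities and run-length statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

TP_GRID_DEG = np.arange(15, 86, 10)   # TP15 … TP85

PARAMETER_COLUMNS = [
    "ND", "TPL", "STA", "PR", "ANGVAR", "TI",
    *[f"TP{d}" for d in TP_GRID_DEG], "avg_speed",
]

#: variables that grow with turning, not with directional persistence; their
#: z-scores enter the composite index with inverted sign so that a larger
#: CDI always means stronger directional migration
TURNING_VARIABLES = frozenset({"ANGVAR", "TI", *[f"TP{d}" for d in TP_GRID_DEG]})


@dataclass
class ProtrusionWindow:
    start_index: int            # 0-based global frame index (= Frame − 1)
    total_frames: int
    phase_frames: tuple         # (E, S, R) frame counts, applied sequentially
    subpath: np.ndarray         # centroid positions inside the window
    truncated: bool = False


def protrusion_window(
    frame: int,
    lifetime_s: float,
    phase_durations_s: tuple,
    centroid_path: np.ndarray,
    frame_interval: float,
) -> ProtrusionWindow:
    """Slice the globally aligned window of one protrusion.

    ``frame`` is the 1-based onset frame; the window is
    [frame−1, frame−1 + round(lifetime/interval)), truncated (and flagged)
    at the track end.
    """
    if frame < 1:
        raise ValueError("onset Frame is 1-based and must be >= 1")
    start = frame - 1
    total = int(round(lifetime_s / frame_interval))
    end = start + total
    truncated = end > len(centroid_path)
    end = min(end, len(centroid_path))
    phase = tuple(int(round(d / frame_interval)) for d in phase_durations_s)
    return ProtrusionWindow(
        start_index=start,
        total_frames=total,
        phase_frames=phase,
        subpath=np.asarray(centroid_path, float)[start:end],
        truncated=truncated,
    )


def phase_slices(window: ProtrusionWindow) -> dict:
    """Sequential E/S/R frame ranges within the window (local indices)."""
    e, s, r = window.phase_frames
    n = len(window.subpath)
    a, b = min(e, n), min(e + s, n)
    return {"E": (0, a), "S": (a, b), "R": (b, min(e + s + r, n))}


def directional_parameters(subpath: np.ndarray, frame_interval: float) -> dict:
    """Directional migration parameters of one window's centroid subpath.

    ND net displacement (µm); TPL total path length (µm); STA = ND/TPL;
    PR mean cosine of turning angles; ANGVAR circular variance of turning
    angles; TI mean |turning angle|/π; TPθ fraction of turning angles above
    θ; avg_speed = TPL / window duration (µm/s).  Turning-based parameters
    need at least 2 steps; with fewer the protrusion is excluded (NaN).
    """
    path = np.asarray(subpath, float)
    if len(path) < 3:
        return {c: np.nan for c in PARAMETER_COLUMNS}
    steps = np.diff(path, axis=0)
    lens = np.linalg.norm(steps, axis=1)
    tpl = float(lens.sum())
    nd = float(np.linalg.norm(path[-1] - path[0]))
    ok = lens > 0
    angles = np.arctan2(steps[:, 1], steps[:, 0])
    turns = []
    prev = None
    for i in range(len(steps)):
        if not ok[i]:
            continue
        if prev is not None:
            d = (angles[i] - prev + np.pi) % (2 * np.pi) - np.pi
            turns.append(d)
        prev = angles[i]
    turns = np.asarray(turns)
    out = {"ND": nd, "TPL": tpl, "STA": nd / tpl if tpl > 0 else np.nan,
           "avg_speed": tpl / ((len(path) - 1) * frame_interval)}
    if len(turns) == 0:
        for c in ("PR", "ANGVAR", "TI", *[f"TP{d}" for d in TP_GRID_DEG]):
            out[c] = np.nan
        return out
    out["PR"] = float(np.cos(turns).mean())
    out["ANGVAR"] = float(1.0 - np.abs(np.exp(1j * turns).mean()))
    out["TI"] = float(np.abs(turns).mean() / np.pi)
    for deg in TP_GRID_DEG:
        out[f"TP{deg}"] = float(np.mean(np.abs(turns) > np.deg2rad(deg)))
    return out


def pca_cdi(params: pd.DataFrame) -> pd.DataFrame:
    """Z-score, SVD PCA, composite directionality index and median split.

    Constant columns are dropped with a warning; PC1's sign is fixed so
    that it correlates non-negatively with net displacement; CDI is the row
    mean of the z-scores with turning-type variables (ANGVAR, TI, TPθ)
    sign-inverted so higher CDI = stronger directional migration;
    protrusions at or below the median CDI go to the low-directionality
    state.

    Returns the input with added ``z_*`` columns, ``PC1``/``PC2`` scores,
    ``CDI`` and ``state``; PC loadings and explained variance are attached
    as ``DataFrame.attrs["pc_loadings"]`` / ``attrs["explained_variance_ratio"]``.
    """
    import warnings

    cols = [c for c in PARAMETER_COLUMNS if c in params.columns]
    data = params[cols].to_numpy(float)
    valid = np.isfinite(data).all(axis=1)
    x = data[valid]
    if len(x) < 2:
        raise ValueError("need at least 2 protrusions with complete parameters")
    sd = x.std(axis=0, ddof=0)
    # near-constant columns would amplify rounding noise when z-scored
    keep = sd > 1e-10 * np.maximum(1.0, np.abs(x.mean(axis=0)))
    if not keep.all():
        dropped = [c for c, k in zip(cols, keep) if not k]
        warnings.warn(f"dropping constant parameter columns: {dropped}")
    cols_kept = [c for c, k in zip(cols, keep) if k]
    z = (x[:, keep] - x[:, keep].mean(axis=0)) / sd[keep]

    u, s, vt = np.linalg.svd(z, full_matrices=False)
    scores = u * s
    nd_idx = cols_kept.index("ND") if "ND" in cols_kept else 0
    for j in range(scores.shape[1]):
        anchor = np.corrcoef(scores[:, j], z[:, nd_idx])[0, 1]
        if np.isfinite(anchor) and anchor < 0:
            scores[:, j] *= -1
            vt[j] *= -1
    orient = np.array([-1.0 if c in TURNING_VARIABLES else 1.0 for c in cols_kept])
    cdi = (z * orient).mean(axis=1)
    median = np.median(cdi)
    state = np.where(cdi > median, "high", "low")

    out = params.copy()
    for j, c in enumerate(cols_kept):
        out.loc[valid, f"z_{c}"] = z[:, j]
    out.loc[valid, "PC1"] = scores[:, 0]
    if scores.shape[1] > 1:
        out.loc[valid, "PC2"] = scores[:, 1]
    out.loc[valid, "CDI"] = cdi
    out.loc[valid, "state"] = state
    out.attrs["pc_loadings"] = pd.DataFrame(vt, columns=cols_kept)
    var = s**2 / np.sum(s**2)
    out.attrs["explained_variance_ratio"] = var
    return out


@dataclass
class TransitionStats:
    transition_matrix: pd.DataFrame      # rows A, cols B: P(A→B)
    transition_counts: pd.DataFrame
    run_lengths: dict                    # state -> list of run lengths
    mean_run_length: dict                # state -> mean


def transitions_and_runs(sequences: list[list[str]],
                         states: tuple = ("high", "low")) -> TransitionStats:
    """First-order transition probabilities and run lengths of protrusion
    state sequences (one ordered sequence per cell, pooled).

    P(A→B) = transitions A→B / all transitions out of A; rows with no
    outgoing transitions are NaN.  Run length = number of consecutive
    same-state protrusions; runs are collected per cell.
    """
    counts = pd.DataFrame(0, index=list(states), columns=list(states), dtype=float)
    runs = {s: [] for s in states}
    for seq in sequences:
        for a, b in zip(seq[:-1], seq[1:]):
            counts.loc[a, b] += 1
        if seq:
            cur, n = seq[0], 1
            for s in seq[1:]:
                if s == cur:
                    n += 1
                else:
                    runs[cur].append(n)
                    cur, n = s, 1
            runs[cur].append(n)
    totals = counts.sum(axis=1)
    probs = counts.div(totals.where(totals > 0), axis=0)
    mean_rl = {s: (float(np.mean(v)) if v else np.nan) for s, v in runs.items()}
    return TransitionStats(probs, counts, runs, mean_rl)


def events_to_directionality(
    events_df: pd.DataFrame,
    tracks: dict,
    frame_interval: float,
) -> pd.DataFrame:
    """Directional-parameter table for a population of protrusions.

    ``events_df`` needs columns cell_id, Frame (1-based), lifetime_s and
    e/s/r durations; ``tracks`` maps cell_id to its centroid path.
    """
    rows = []
    for _, ev in events_df.iterrows():
        path = tracks[ev["cell_id"]]
        win = protrusion_window(
            int(ev["Frame"]), float(ev["lifetime_s"]),
            (ev.get("e_duration", 0.0), ev.get("s_duration", 0.0), ev.get("r_duration", 0.0)),
            path, frame_interval,
        )
        p = directional_parameters(win.subpath, frame_interval)
        rows.append({"cell_id": ev["cell_id"], "Frame": ev["Frame"],
                     "start_index": win.start_index, "truncated": win.truncated, **p})
    return pd.DataFrame(rows)
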