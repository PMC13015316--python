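"""Detection, tracking, classification and myosin-II quantification of
high-curvature protrusions.

A new protrusion is born at a maximal run of consecutive boundary points
whose curvature exceeds 0.2 µm⁻¹, provided its center (the peak-curvature
point with a half width of 2 points per side, a 5-point window) does not
map — through the boundary point tracking — onto any qualifying region of
the previous frame.  The protrusion's per-frame rate is the total local
area change over its 5-point center; the lifetime runs until the first
frame at which that rate turns negative (retraction onset).  Protrusions
are classed as transient (lifetime below one 6 s frame), stable (longer),
and, within the stable pool, long-life (above 30 s).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .boundary import N_POINTS, BoundaryKinematics

CURVATURE_THRESHOLD = 0.2    # µm⁻¹
CENTER_HALF_WIDTH = 2        # boundary points per side; 5-point center
STABLE_CUT_S = 6.0           # s; lifetime above this → stable
LONG_LIFE_CUT_S = 30.0       # s; stable lifetime above this → long_life


@dataclass
class ProtrusionEvent:
    cell_id: int
    birth_frame: int                     # 0-based global frame index
    center_trace: dict = field(default_factory=dict)   # frame -> center point index
    lifetime_s: float = np.nan
    lifetime_frames: int = 0
    censored: bool = False
    cls: str | None = None
    expansion_rate: float = np.nan       # µm²/s
    disassembly_rate: float = np.nan     # µm²/s
    e_duration: float = np.nan           # s, rate-profile surrogate phases
    s_duration: float = np.nan
    r_duration: float = np.nan
    steady_epsilon: float = np.nan       # recorded steady-stage cutoff used
    birth_region: str | None = None
    nmii_trace: np.ndarray | None = None
    mean_nmii: float = np.nan
    nmii_localization_lifetime: dict = field(default_factory=dict)

    @property
    def frame(self) -> int:
        """1-based global onset frame (the table's "Frame" column)."""
        return self.birth_frame + 1


def _center_window(idx: int) -> np.ndarray:
    return (idx + np.arange(-CENTER_HALF_WIDTH, CENTER_HALF_WIDTH + 1)) % N_POINTS


def curvature_regions(kappa: np.ndarray, threshold: float = CURVATURE_THRESHOLD):
    """Maximal cyclic runs of points with curvature above threshold.

    Returns a list of (indices, peak_index) with indices in boundary order.
    """
    above = np.asarray(kappa) > threshold
    n = len(above)
    if above.all():
        idx = np.arange(n)
        return [(idx, int(np.argmax(kappa)))]
    regions = []
    # start scanning after a below-threshold point so cyclic runs stay whole
    start = int(np.argmin(above))
    run: list[int] = []
    for off in range(1, n + 1):
        i = (start + off) % n
        if above[i]:
            run.append(i)
        elif run:
            idx = np.array(run)
            regions.append((idx, int(idx[np.argmax(kappa[idx])])))
            run = []
    if run:
        idx = np.array(run)
        regions.append((idx, int(idx[np.argmax(kappa[idx])])))
    return regions


def detect_and_track(
    kin: BoundaryKinematics,
    frame_interval: float,
    cell_id: int = 0,
    curvature_threshold: float = CURVATURE_THRESHOLD,
    retraction_tolerance: float = 0.0,
    steady_epsilon_frac: float = 0.1,
) -> list[ProtrusionEvent]:
    """Detect protrusion births and track their centers through the movie.

    Birth requires the 5-point center of a qualifying region, mapped
    backwards through the boundary-point correspondence, to share no point
    with any qualifying region of the previous frame.  After birth the
    center follows the overlapping qualifying region of the next frame (or
    the bare point correspondence once the curvature drops), and per-event
    rates, lifetime, class and rate-profile phase durations are extracted.
    """
    kappa, shifts = kin.curvature, kin.shifts
    t_len = kappa.shape[0]
    regions = [curvature_regions(kappa[t], curvature_threshold) for t in range(t_len)]

    events: list[ProtrusionEvent] = []
    for t in range(t_len):
        prev_points = (
            np.concatenate([idx for idx, _ in regions[t - 1]]) if t > 0 and regions[t - 1] else np.array([], int)
        )
        for idx, peak in regions[t]:
            center = _center_window(peak)
            if t > 0:
                back = (center - shifts[t - 1]) % N_POINTS
                if np.isin(back, prev_points).any():
                    continue
            events.append(ProtrusionEvent(cell_id=cell_id, birth_frame=t,
                                          center_trace={t: peak}))

    for ev in events:
        _track_event(ev, regions, shifts, t_len)
        _event_rates(ev, kin, frame_interval, retraction_tolerance, steady_epsilon_frac)
    return events


def _track_event(ev: ProtrusionEvent, regions, shifts, t_len: int) -> None:
    c = ev.center_trace[ev.birth_frame]
    for t in range(ev.birth_frame, t_len - 1):
        mapped = (_center_window(c) + shifts[t]) % N_POINTS
        nxt = None
        for idx, peak in regions[t + 1]:
            if np.isin(mapped, idx).any():
                nxt = peak
                break
        c = nxt if nxt is not None else int((c + shifts[t]) % N_POINTS)
        ev.center_trace[t + 1] = c


def _center_rate(ev: ProtrusionEvent, kin: BoundaryKinematics, t: int, dt: float) -> float:
    """Protrusion rate at frame t: total a_k over the 5-point center, per s."""
    w = _center_window(ev.center_trace[t])
    return float(kin.area_change[t, w].sum()) / dt


def _event_rates(
    ev: ProtrusionEvent,
    kin: BoundaryKinematics,
    dt: float,
    tol: float,
    eps_frac: float,
) -> None:
    t_len = kin.curvature.shape[0]
    b = ev.birth_frame
    last_rate_frame = t_len - 2          # rate(t) uses the t -> t+1 change
    rates = {t: _center_rate(ev, kin, t, dt) for t in range(b, last_rate_frame + 1)}

    t_retract = None
    for t in range(b, last_rate_frame + 1):
        if rates[t] < -tol:
            t_retract = t
            break
    if t_retract is None:
        ev.censored = True
        ev.lifetime_frames = last_rate_frame + 1 - b
        ev.lifetime_s = ev.lifetime_frames * dt
    else:
        ev.lifetime_frames = t_retract - b
        ev.lifetime_s = ev.lifetime_frames * dt

    if ev.lifetime_s > LONG_LIFE_CUT_S:
        ev.cls = "long_life"
    elif ev.lifetime_s > STABLE_CUT_S:
        ev.cls = "stable"
    else:
        ev.cls = "transient"

    grow = [rates[t] for t in range(b, (t_retract if t_retract is not None else last_rate_frame + 1))]
    if grow:
        peak = max(grow)
        eps = eps_frac * peak if peak > 0 else 0.0
        ev.steady_epsilon = eps
        steady_onset = len(grow)
        for j, r in enumerate(grow):
            if r < eps:
                steady_onset = j
                break
        pos = grow[:steady_onset]
        ev.expansion_rate = float(np.mean(pos)) if pos else np.nan
        ev.e_duration = steady_onset * dt
        ev.s_duration = (len(grow) - steady_onset) * dt
    if not ev.censored and t_retract is not None:
        neg = []
        for t in range(t_retract, last_rate_frame + 1):
            r = rates[t]
            if r < -tol:
                neg.append(r)
            else:
                break
        ev.disassembly_rate = float(np.mean(neg)) if neg else np.nan
        ev.r_duration = len(neg) * dt


def protrusion_frequency(events: list[ProtrusionEvent], total_time: float) -> dict:
    """New-protrusion frequency (s⁻¹), overall and per class."""
    if total_time <= 0:
        raise ValueError("total migration time must be > 0")
    out = {"all": len(events) / total_time}
    for cls in ("transient", "stable", "long_life"):
        out[cls] = sum(1 for e in events if e.cls == cls) / total_time
    # long-life protrusions are a subset of the stable pool
    out["stable"] += out["long_life"]
    return out


def protrusion_nmii(
    ev: ProtrusionEvent,
    i_norm: np.ndarray,
    counts: np.ndarray,
    frame_interval: float,
    thresholds: tuple = (1.1,),
) -> None:
    """Cortical myosin-II engagement of one protrusion.

    I'_protrusion(t) is the voxel-weighted mean of the normalized level over
    the window i = k*−2 … k*+1 around the center index k*(t), evaluated on
    the frames of the protrusion lifetime.  Also fills the mean level and,
    per threshold, the localization lifetime (longest consecutive run above
    the threshold, in seconds).
    """
    frames = [t for t in range(ev.birth_frame, ev.birth_frame + ev.lifetime_frames + 1)
              if t in ev.center_trace and t < i_norm.shape[0]]
    if not frames:
        ev.nmii_trace = None
        return
    trace = np.empty(len(frames))
    for j, t in enumerate(frames):
        k = ev.center_trace[t]
        idx = (k + np.arange(-2, 2)) % N_POINTS
        w = counts[t, idx]
        tot = w.sum()
        trace[j] = np.nansum(i_norm[t, idx] * w) / tot if tot > 0 else np.nan
    ev.nmii_trace = trace
    ev.mean_nmii = float(np.nanmean(trace))
    for thr in thresholds:
        best = run = 0
        for v in trace:
            run = run + 1 if np.isfinite(v) and v > thr else 0
            best = max(best, run)
        ev.nmii_localization_lifetime[thr] = best * frame_interval
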