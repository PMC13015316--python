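"""Per-point boundary kinematics and cortical myosin-II quantification.

Given the 100-point subpixel boundary of a tracked cell, this module
computes per-point signed membrane motion and local area change between
frames, local curvature by Pratt circle fitting over an 11-point window,
the 100 cortical sections of the 2 µm subcortical shell with their raw and
normalized fluorescence levels, and the front / rear / side partition of
the boundary relative to the migration direction.

Conventions: boundaries are counterclockwise; curvature is positive where
the boundary bulges outward; membrane motion is positive outward; all
index arithmetic is cyclic modulo 100.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import shapely
from scipy import linalg, ndimage
from scipy.spatial import cKDTree
from shapely.geometry import Polygon

N_POINTS = 100
CURVATURE_WINDOW_SIDE = 5      # neighbors per side for the circle fit (11 total)
CORTEX_DEPTH = 2.0             # µm
FRONT_SIZE, REAR_SIZE, SIDE_SIZE = 30, 30, 20


# ---------------------------------------------------------------------------
# curvature

def pratt_circle_fit(points: np.ndarray):
    """Algebraic (Pratt) circle fit.

    Minimizes the algebraic distance ``A(x²+y²)+Bx+Cy+D`` under the Pratt
    normalization ``B²+C²−4AD=1``.  Returns (center, radius); radius is
    ``inf`` for collinear points (A → 0).
    """
    pts = np.asarray(points, dtype=float)
    x, y = pts[:, 0] - pts[:, 0].mean(), pts[:, 1] - pts[:, 1].mean()
    z = x * x + y * y
    zm = np.column_stack([z, x, y, np.ones_like(x)])
    m = zm.T @ zm / len(x)
    b = np.array(
        [[0.0, 0.0, 0.0, -2.0],
         [0.0, 1.0, 0.0, 0.0],
         [0.0, 0.0, 1.0, 0.0],
         [-2.0, 0.0, 0.0, 0.0]]
    )
    vals, vecs = linalg.eig(m, b)
    vals = np.real(vals)
    # smallest non-negative generalized eigenvalue gives the Pratt solution
    vals[vals < -1e-12] = np.inf
    v = np.real(vecs[:, np.argmin(vals)])
    a, bb, cc, d = v
    if abs(a) < 1e-12 * max(1.0, abs(bb) + abs(cc)):
        return np.array([np.nan, np.nan]), np.inf
    cx, cy = -bb / (2 * a), -cc / (2 * a)
    r = np.sqrt(max(bb * bb + cc * cc - 4 * a * d, 0.0)) / (2 * abs(a))
    return np.array([cx + pts[:, 0].mean(), cy + pts[:, 1].mean()]), r


def local_curvature(points: np.ndarray, side: int = CURVATURE_WINDOW_SIDE) -> np.ndarray:
    """Signed curvature κ_k (µm⁻¹) at each of the 100 boundary points.

    κ = 1/R from the Pratt fit over the window of ``side`` neighbors per
    side; the sign is positive where the (counterclockwise) boundary turns
    left, i.e. at outward-convex regions such as protrusions.
    """
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    kappa = np.zeros(n)
    idx = np.arange(-side, side + 1)
    for k in range(n):
        window = pts[(k + idx) % n]
        _, r = pratt_circle_fit(window)
        if not np.isfinite(r) or r <= 0:
            kappa[k] = 0.0
            continue
        v1 = pts[k] - pts[(k - side) % n]
        v2 = pts[(k + side) % n] - pts[k]
        sign = 1.0 if (v1[0] * v2[1] - v1[1] * v2[0]) >= 0 else -1.0
        kappa[k] = sign / r
    return kappa


# ---------------------------------------------------------------------------
# point tracking and kinematics

def track_boundary_points(prev: np.ndarray, nxt: np.ndarray):
    """Minimum-displacement correspondence between consecutive boundaries.

    Both frames carry 100 evenly spaced counterclockwise points, so the
    order-preserving assignment reduces to the cyclic shift minimizing the
    total displacement.  Returns (shift, motion) where ``nxt[(k+shift) %
    100]`` corresponds to ``prev[k]`` and ``motion[k]`` is the signed
    displacement in µm (positive outward from the cell).
    """
    prev = np.asarray(prev, float)
    nxt = np.asarray(nxt, float)
    n = len(prev)
    if n < 3 or len(nxt) != n:
        raise ValueError("degenerate boundary polygons")
    best_s, best_cost = 0, np.inf
    for s in range(n):
        cost = np.linalg.norm(np.roll(nxt, -s, axis=0) - prev, axis=1).sum()
        if cost < best_cost:
            best_cost, best_s = cost, s
    matched = np.roll(nxt, -best_s, axis=0)
    disp = np.linalg.norm(matched - prev, axis=1)
    poly = Polygon(prev)
    inside = shapely.contains_xy(poly, matched[:, 0], matched[:, 1])
    motion = np.where(inside, -disp, disp)
    return best_s, motion


def local_area_change(prev: np.ndarray, nxt: np.ndarray, shift: int, motion: np.ndarray):
    """Signed local area change a_k (µm²) per boundary point.

    For each point the swept region is the hexagon whose vertices are the
    tracked point in the current and next frame and the midpoints to its
    clockwise and counterclockwise neighbors in both frames.  The area is
    the absolute shoelace value of that polygon, signed like the point's
    membrane motion.  Self-intersecting local polygons are flagged.
    """
    prev = np.asarray(prev, float)
    matched = np.roll(np.asarray(nxt, float), -shift, axis=0)
    n = len(prev)
    a = np.zeros(n)
    flags = np.zeros(n, dtype=bool)
    for k in range(n):
        pm1, p, pp1 = prev[(k - 1) % n], prev[k], prev[(k + 1) % n]
        qm1, q, qp1 = matched[(k - 1) % n], matched[k], matched[(k + 1) % n]
        hexagon = np.array([
            0.5 * (pm1 + p), p, 0.5 * (p + pp1),
            0.5 * (q + qp1), q, 0.5 * (qm1 + q),
        ])
        x, y = hexagon[:, 0], hexagon[:, 1]
        area = 0.5 * abs(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))
        if not Polygon(hexagon).is_valid:
            flags[k] = True
        a[k] = np.sign(motion[k]) * area if motion[k] != 0 else 0.0
    return a, flags


def polygon_area(points: np.ndarray) -> float:
    x, y = points[:, 0], points[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


# ---------------------------------------------------------------------------
# cortical sections

@dataclass
class CorticalSections:
    """Raw cortical section statistics over a whole track.

    Arrays are (T, 100) for per-section quantities and (T,) for cell-level
    quantities; ``counts`` are voxel counts N_k(t).
    """

    raw: np.ndarray
    counts: np.ndarray
    cell_mean: np.ndarray
    unassigned_raw: np.ndarray
    unassigned_counts: np.ndarray
    flags: np.ndarray | None = None


def build_cortical_sections_frame(
    boundary: np.ndarray,
    mask3d: np.ndarray,
    intensity3d: np.ndarray,
    voxel_size_xy: float,
    origin: tuple = (0.0, 0.0),
    cortex_depth: float = CORTEX_DEPTH,
):
    """Cortical section statistics for one frame.

    Every cell voxel whose (y, x) column z-projects within ``cortex_depth``
    µm of the 2-D boundary is assigned to the section of the nearest
    boundary point; the remaining cell voxels form the unassigned region.

    Returns (N_k, I_raw_k, cell_mean, N_unassigned, I_raw_unassigned).
    """
    zz, yy, xx = np.nonzero(mask3d)
    if len(zz) == 0:
        raise ValueError("empty mask")
    vals = intensity3d[zz, yy, xx].astype(float)
    cell_mean = float(vals.mean())

    px = np.column_stack([
        origin[0] + (xx + 0.5) * voxel_size_xy,
        origin[1] + (yy + 0.5) * voxel_size_xy,
    ])
    # dense boundary for an accurate distance-to-contour estimate
    from .simulate import _resample_closed

    dense = _resample_closed(boundary, 1000)
    dist, _ = cKDTree(dense).query(px)
    _, sec_idx = cKDTree(boundary).query(px)
    in_cortex = dist <= cortex_depth

    n_k = np.zeros(N_POINTS)
    raw_k = np.zeros(N_POINTS)
    np.add.at(n_k, sec_idx[in_cortex], 1.0)
    np.add.at(raw_k, sec_idx[in_cortex], vals[in_cortex])
    with np.errstate(invalid="ignore"):
        raw_k = np.where(n_k > 0, raw_k / np.maximum(n_k, 1), np.nan)
    n_un = float((~in_cortex).sum())
    raw_un = float(vals[~in_cortex].mean()) if n_un else np.nan
    return n_k, raw_k, cell_mean, n_un, raw_un


def sections_from_field(boundary_values: np.ndarray) -> CorticalSections:
    """Wrap per-point cortical field samples (T, 100) as unit-count sections.

    Supports the direct (render-free) analysis route on synthetic boundary
    and intensity tables.
    """
    raw = np.asarray(boundary_values, float)
    counts = np.ones_like(raw)
    return CorticalSections(
        raw=raw,
        counts=counts,
        cell_mean=raw.mean(axis=1),
        unassigned_raw=np.full(raw.shape[0], np.nan),
        unassigned_counts=np.zeros(raw.shape[0]),
    )


# ---------------------------------------------------------------------------
# normalization

def normalize_intensity(sections: CorticalSections, smoothing: str = "printed"):
    """Normalized cortical levels I_k(t) and smoothed I'_k(t).

    I_k(t) = (I_raw,k(t) − I_raw,min) / (I_raw,mean(t) − I_raw,min), with
    I_raw,min the per-cell minimum over all sections and times.  I'_k is the
    voxel-count-weighted average over the window i = k−2 … k+1 (cyclic);
    ``smoothing="symmetric"`` selects the 5-section window k−2 … k+2
    instead.

    Returns (I, I_prime, flat_flags) where ``flat_flags`` marks frames with
    I_raw,mean(t) equal to I_raw,min (normalization undefined).
    """
    raw, counts = sections.raw, sections.counts
    raw_min = np.nanmin(raw)
    denom = sections.cell_mean - raw_min
    flat = denom <= 0
    denom = np.where(flat, np.nan, denom)
    i_norm = (raw - raw_min) / denom[:, None]

    offsets = np.arange(-2, 2) if smoothing == "printed" else np.arange(-2, 3)
    t_len = raw.shape[0]
    i_prime = np.empty_like(i_norm)
    for k in range(N_POINTS):
        idx = (k + offsets) % N_POINTS
        w = counts[:, idx]
        num = np.nansum(i_norm[:, idx] * w, axis=1)
        den = w.sum(axis=1)
        i_prime[:, k] = np.where(den > 0, num / np.maximum(den, 1e-300), np.nan)
    return i_norm, i_prime, flat


def normalize_unassigned(sections: CorticalSections) -> np.ndarray:
    """Normalized level of the cell region outside all cortical sections."""
    raw_min = np.nanmin(sections.raw)
    denom = sections.cell_mean - raw_min
    denom = np.where(denom <= 0, np.nan, denom)
    return (sections.unassigned_raw - raw_min) / denom


# ---------------------------------------------------------------------------
# region partition

@dataclass
class RegionAssignment:
    front: np.ndarray        # 30 point indices
    rear: np.ndarray         # 30
    side_left: np.ndarray    # 20
    side_right: np.ndarray   # 20
    front_width: float       # µm
    rear_width: float        # µm
    defined: bool = True

    def labels(self) -> np.ndarray:
        lab = np.empty(N_POINTS, dtype=object)
        lab[self.front] = "front"
        lab[self.rear] = "rear"
        lab[self.side_left] = "side"
        lab[self.side_right] = "side"
        return lab


def assign_regions(boundary: np.ndarray, direction: np.ndarray) -> RegionAssignment:
    """Partition the 100 boundary points into front (30), rear (30) and two
    sides (20 each) relative to the migration direction.

    The rear arc is centered on the point whose outward direction is most
    anti-parallel to the migration direction ``direction``; the front arc is
    antipodal; widths are the spans of each arc perpendicular to the
    migration direction.
    """
    direction = np.asarray(direction, float)
    nrm = np.linalg.norm(direction)
    if not np.isfinite(nrm) or nrm == 0:
        empty = np.array([], dtype=int)
        return RegionAssignment(empty, empty, empty, empty, np.nan, np.nan, defined=False)
    n_hat = direction / nrm
    centroid = boundary.mean(axis=0)
    outward = boundary - centroid
    outward /= np.linalg.norm(outward, axis=1, keepdims=True)
    k_rear = int(np.argmin(outward @ n_hat))

    half = REAR_SIZE // 2
    rear = (k_rear + np.arange(-half, REAR_SIZE - half)) % N_POINTS
    front = (rear + N_POINTS // 2) % N_POINTS
    # walk counterclockwise from the end of one arc to the start of the other
    rear_end = (k_rear + REAR_SIZE - half) % N_POINTS
    side_a = (rear_end + np.arange(SIDE_SIZE)) % N_POINTS
    front_end = (front[-1] + 1) % N_POINTS
    side_b = (front_end + np.arange(SIDE_SIZE)) % N_POINTS

    perp = np.array([-n_hat[1], n_hat[0]])
    front_width = float(np.ptp(boundary[front] @ perp))
    rear_width = float(np.ptp(boundary[rear] @ perp))
    return RegionAssignment(front, rear, side_a, side_b, front_width, rear_width)


@dataclass
class BoundaryKinematics:
    """Whole-track per-point kinematics.

    ``curvature`` is (T, 100); ``shifts`` (T−1,) are the cyclic index
    offsets aligning frame t+1 to frame t; ``motion`` and ``area_change``
    are (T−1, 100), indexed by the frame-t point index.
    """

    curvature: np.ndarray
    shifts: np.ndarray
    motion: np.ndarray
    area_change: np.ndarray
    flags: np.ndarray


def compute_kinematics(points: np.ndarray) -> BoundaryKinematics:
    """Curvature, point correspondence, signed motion and local area change
    for a (T, 100, 2) boundary series."""
    pts = np.asarray(points, float)
    t_len = pts.shape[0]
    kappa = np.array([local_curvature(pts[t]) for t in range(t_len)])
    shifts = np.zeros(t_len - 1, dtype=int)
    motion = np.zeros((t_len - 1, N_POINTS))
    area = np.zeros((t_len - 1, N_POINTS))
    flags = np.zeros((t_len - 1, N_POINTS), dtype=bool)
    for t in range(t_len - 1):
        s, m = track_boundary_points(pts[t], pts[t + 1])
        a, f = local_area_change(pts[t], pts[t + 1], s, m)
        shifts[t], motion[t], area[t], flags[t] = s, m, a, f
    return BoundaryKinematics(kappa, shifts, motion, area, flags)


def region_levels(
    i_norm_frame: np.ndarray,
    counts_frame: np.ndarray,
    regions: RegionAssignment,
) -> dict:
    """Voxel-weighted normalized level I'_part per cortical region for one
    frame: I'_part = Σ_{k∈part} I_k N_k / Σ_{k∈part} N_k."""
    if not regions.defined:
        return {"front": np.nan, "rear": np.nan, "side": np.nan}
    out = {}
    for name, idx in (
        ("front", regions.front),
        ("rear", regions.rear),
        ("side", np.concatenate([regions.side_left, regions.side_right])),
    ):
        w = counts_frame[idx]
        tot = w.sum()
        out[name] = float(np.nansum(i_norm_frame[idx] * w) / tot) if tot > 0 else np.nan
    return out
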