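"""Synthetic amoeboid-cell time-lapse generator.

Produces star-convex cells (~10-12 µm) migrating as a correlated random
walk, with scripted high-curvature protrusions that follow an
expansion / stabilization / retraction (E/S/R) amplitude schedule, a
rear-enriched cortical myosin pool, a fluctuating front pool, and
configurable imaging noise.  Every downstream stage of the pipeline can be
validated against the ground truth emitted here, either through rendered
voxel movies or directly through the boundary/intensity tables (bypassing
segmentation).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .io import TimeLapse

TWO_PI = 2.0 * np.pi

#: fraction of the 100 boundary points assigned to front / rear arcs
FRONT_ARC_HALF_ANGLE = 0.30 * np.pi  # 30 of 100 points


def _wrap_angle(a: np.ndarray | float) -> np.ndarray | float:
    """Wrap angle(s) to (-pi, pi]."""
    return (np.asarray(a) + np.pi) % TWO_PI - np.pi


def raised_cosine(delta: np.ndarray, half_width: float) -> np.ndarray:
    """Smooth unimodal angular bump profile, 1 at delta=0, 0 outside ±half_width."""
    u = _wrap_angle(delta) / half_width
    out = 0.5 * (1.0 + np.cos(np.pi * u))
    return np.where(np.abs(u) < 1.0, out, 0.0)


@dataclass(frozen=True)
class ProtrusionScript:
    """One scripted protrusion event.

    Durations are in seconds; the amplitude ramps up linearly over the
    expansion phase, holds during stabilization, and decays linearly to zero
    over the retraction phase (the first retraction frame still holds the
    plateau amplitude, so the measured "keep protruding or staying" lifetime
    equals E + S).
    """

    birth_frame: int
    angle: float | None          # angular position, rad; None = cell front at birth
    amplitude: float             # peak radial amplitude, µm
    e_duration: float            # expansion, s
    s_duration: float            # stabilization, s
    r_duration: float            # retraction, s
    half_width: float = 0.35     # angular half width of the bump, rad

    @property
    def lifetime(self) -> float:
        """Full scripted lifetime E+S+R in seconds."""
        return self.e_duration + self.s_duration + self.r_duration

    @property
    def es_lifetime(self) -> float:
        """Expansion + stabilization duration (time before retraction), s."""
        return self.e_duration + self.s_duration


@dataclass
class SimulationParams:
    n_frames: int = 20
    frame_interval: float = 6.0          # s
    voxel_size_xy: float = 0.5           # µm / pixel
    voxel_size_z: float = 1.0            # µm / plane
    n_z: int = 1
    cell_radius: float = 6.0             # µm
    centroid_speed: float = 0.2          # µm / s
    direction_persistence: float = 0.8   # step-to-step heading correlation in [0, 1]
    protrusion_schedule: list[ProtrusionScript] = field(default_factory=list)
    cortex_base_level: float = 1.0       # a.u., uniform cortical background
    interior_level: float = 0.8          # a.u., cytoplasm inside the cortex shell
    rear_pool_level: float = 2.0         # a.u., added opposite the heading
    front_pool_level: float = 1.0        # a.u., added along the heading
    front_pool_fluctuation: float = 0.3  # a.u., s.d. of per-frame front pool noise
    pool_half_width: float = np.pi / 3.0  # angular extent of each pool, rad
    cortex_depth: float = 2.0            # µm
    noise_gaussian_sigma: float = 0.05   # a.u.
    noise_poisson_gain: float = 0.0      # photons per a.u.; 0 disables shot noise
    psf_sigma: float = 0.2               # µm
    seed: int = 0

    def validate(self) -> None:
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.frame_interval <= 0 or self.voxel_size_xy <= 0:
            raise ValueError("frame_interval and voxel sizes must be > 0")
        if not (0.0 <= self.direction_persistence <= 1.0):
            raise ValueError("direction_persistence must be in [0, 1]")
        for ev in self.protrusion_schedule:
            if ev.amplitude < 0:
                raise ValueError("protrusion amplitudes must be >= 0")
            if ev.amplitude > self.cell_radius:
                raise ValueError(
                    "protrusion amplitude exceeds the base radius; the "
                    "boundary would no longer be star-convex"
                )
            if min(ev.e_duration, ev.s_duration, ev.r_duration) <= 0:
                raise ValueError("E/S/R durations must be > 0")


@dataclass
class BoundarySeries:
    """Per-frame 100-point boundary polygons in µm (n_frames, 100, 2)."""

    points: np.ndarray
    frame_interval: float

    @property
    def n_frames(self) -> int:
        return self.points.shape[0]


@dataclass
class IntensitySeries:
    """Noise-free cortical intensity field, parametrized per frame.

    The field is angular: intensity at boundary angle theta (about the
    centroid) is ``base + rear_amp * rc(theta - rear_angle) +
    front_amp * rc(theta - front_angle)``.
    """

    base: float
    interior_level: float
    pool_half_width: float
    headings: np.ndarray        # (T,) rad
    rear_amps: np.ndarray       # (T,)
    front_amps: np.ndarray      # (T,)
    boundary_values: np.ndarray  # (T, 100) field sampled at boundary points

    def value(self, theta: np.ndarray, frame: int) -> np.ndarray:
        h = self.headings[frame]
        return (
            self.base
            + self.rear_amps[frame] * raised_cosine(theta - (h + np.pi), self.pool_half_width)
            + self.front_amps[frame] * raised_cosine(theta - h, self.pool_half_width)
        )


@dataclass
class SyntheticGroundTruth:
    centroid_path: np.ndarray      # (T, 2) µm
    headings: np.ndarray           # (T,) rad
    boundaries: np.ndarray         # (T, 100, 2) µm
    events: pd.DataFrame           # one row per scripted event
    region_intensity: pd.DataFrame  # per-frame front/rear/side mean (pre-noise)
    params: SimulationParams


def _event_amplitude(ev: ProtrusionScript, frame: int, dt: float) -> float:
    """Amplitude of a scripted event at a given frame (0 when inactive)."""
    elapsed = (frame - ev.birth_frame) * dt
    if elapsed < 0 or elapsed >= ev.lifetime - 0.5 * dt:
        return 0.0
    n_e = max(int(round(ev.e_duration / dt)), 1)
    n_s = max(int(round(ev.s_duration / dt)), 1)
    n_r = max(int(round(ev.r_duration / dt)), 1)
    i = int(round(elapsed / dt))
    if i < n_e:                       # expansion: linear ramp up to amplitude
        return ev.amplitude * (i + 1) / n_e
    if i < n_e + n_s:                 # stabilization: plateau
        return ev.amplitude
    j = i - n_e - n_s                 # retraction: decay from the plateau
    if j >= n_r:
        return 0.0
    return ev.amplitude * (n_r - 1 - j) / max(n_r - 1, 1)


def _radial_profile(schedule, params: SimulationParams, frame: int,
                    theta: np.ndarray) -> np.ndarray:
    r = np.full_like(theta, params.cell_radius, dtype=float)
    for ev in schedule:
        a = _event_amplitude(ev, frame, params.frame_interval)
        if a > 0:
            r = r + a * raised_cosine(theta - ev.angle, ev.half_width)
    return r


def _resample_closed(points: np.ndarray, n: int) -> np.ndarray:
    """Resample a closed polygon to n points evenly spaced in arc length."""
    closed = np.vstack([points, points[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    target = np.linspace(0.0, s[-1], n, endpoint=False)
    x = np.interp(target, s, closed[:, 0])
    y = np.interp(target, s, closed[:, 1])
    return np.column_stack([x, y])


def _correlated_walk(params: SimulationParams, rng: np.random.Generator):
    """Centroid path and headings of a correlated random walk."""
    step = params.centroid_speed * params.frame_interval
    headings = np.empty(params.n_frames)
    headings[0] = rng.uniform(-np.pi, np.pi)
    rho = params.direction_persistence
    if rho >= 1.0:
        turns = np.zeros(params.n_frames - 1)
    elif rho <= 0.0:
        turns = rng.uniform(-np.pi, np.pi, params.n_frames - 1)
    else:
        # wrapped-normal turning angle: E[cos] = exp(-sigma^2/2) = rho
        sigma = np.sqrt(-2.0 * np.log(rho))
        turns = rng.normal(0.0, sigma, params.n_frames - 1)
    for t in range(1, params.n_frames):
        headings[t] = _wrap_angle(headings[t - 1] + turns[t - 1])
    path = np.zeros((params.n_frames, 2))
    for t in range(1, params.n_frames):
        path[t] = path[t - 1] + step * np.array(
            [np.cos(headings[t - 1]), np.sin(headings[t - 1])]
        )
    return path, headings


def simulate_cell(params: SimulationParams):
    """Simulate one cell; returns (BoundarySeries, IntensitySeries, SyntheticGroundTruth).

    Deterministic for a fixed ``params.seed``.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    path, headings = _correlated_walk(params, rng)

    # events without a scripted angle form at the cell front (pseudopods
    # extend along the heading at their birth frame)
    schedule = [
        dataclasses.replace(
            ev, angle=float(headings[min(ev.birth_frame, params.n_frames - 1)])
        )
        if ev.angle is None
        else ev
        for ev in params.protrusion_schedule
    ]

    dense_theta = np.linspace(-np.pi, np.pi, 720, endpoint=False)
    boundaries = np.empty((params.n_frames, 100, 2))
    for t in range(params.n_frames):
        r = _radial_profile(schedule, params, t, dense_theta)
        poly = np.column_stack([r * np.cos(dense_theta), r * np.sin(dense_theta)])
        boundaries[t] = _resample_closed(poly, 100) + path[t]

    front_fluct = rng.normal(0.0, params.front_pool_fluctuation, params.n_frames)
    front_amps = np.clip(params.front_pool_level + front_fluct, 0.0, None)
    rear_amps = np.full(params.n_frames, params.rear_pool_level)

    boundary_values = np.empty((params.n_frames, 100))
    region_rows = []
    for t in range(params.n_frames):
        rel = boundaries[t] - path[t]
        theta = np.arctan2(rel[:, 1], rel[:, 0])
        h = headings[t]
        vals = (
            params.cortex_base_level
            + rear_amps[t] * raised_cosine(theta - (h + np.pi), params.pool_half_width)
            + front_amps[t] * raised_cosine(theta - h, params.pool_half_width)
        )
        boundary_values[t] = vals
        d_front = np.abs(_wrap_angle(theta - h))
        front = d_front <= FRONT_ARC_HALF_ANGLE
        rear = d_front >= np.pi - FRONT_ARC_HALF_ANGLE
        side = ~(front | rear)
        region_rows.append(
            {
                "frame": t,
                "front_mean": float(vals[front].mean()),
                "rear_mean": float(vals[rear].mean()),
                "side_mean": float(vals[side].mean()),
            }
        )

    intensity = IntensitySeries(
        base=params.cortex_base_level,
        interior_level=params.interior_level,
        pool_half_width=params.pool_half_width,
        headings=headings,
        rear_amps=rear_amps,
        front_amps=front_amps,
        boundary_values=boundary_values,
    )

    events = pd.DataFrame(
        [
            {
                "birth_frame": ev.birth_frame,
                "angle": ev.angle,
                "amplitude": ev.amplitude,
                "e_duration": ev.e_duration,
                "s_duration": ev.s_duration,
                "r_duration": ev.r_duration,
                "lifetime": ev.lifetime,
                "es_lifetime": ev.es_lifetime,
            }
            for ev in schedule
        ],
        columns=[
            "birth_frame", "angle", "amplitude", "e_duration", "s_duration",
            "r_duration", "lifetime", "es_lifetime",
        ],
    )

    truth = SyntheticGroundTruth(
        centroid_path=path,
        headings=headings,
        boundaries=boundaries,
        events=events,
        region_intensity=pd.DataFrame(region_rows),
        params=params,
    )
    series = BoundarySeries(points=boundaries, frame_interval=params.frame_interval)
    return series, intensity, truth


def render_movie(
    boundaries: BoundarySeries,
    intensities: IntensitySeries,
    params: SimulationParams,
    margin: float = 4.0,
) -> TimeLapse:
    """Rasterize a simulated cell into a calibrated T×C×Z×Y×X stack.

    The intensity field is painted inside the true polygon (cortex value in
    the 2 µm shell, interior level elsewhere), blurred by a Gaussian PSF of
    ``psf_sigma`` and degraded by the configured noise.  Background is zero.
    """
    from scipy import ndimage
    from skimage.draw import polygon as draw_polygon

    if boundaries.n_frames == 0:
        raise ValueError("empty boundary series")
    if boundaries.n_frames != params.n_frames:
        raise ValueError("boundary series length does not match n_frames")

    rng = np.random.default_rng(params.seed + 1)
    px = params.voxel_size_xy
    pts = boundaries.points
    lo = pts.reshape(-1, 2).min(axis=0) - margin
    hi = pts.reshape(-1, 2).max(axis=0) + margin
    nx = int(np.ceil((hi[0] - lo[0]) / px))
    ny = int(np.ceil((hi[1] - lo[1]) / px))

    data = np.zeros((params.n_frames, 1, params.n_z, ny, nx), dtype=np.float32)
    yy, xx = np.mgrid[0:ny, 0:nx]
    px_x = lo[0] + (xx + 0.5) * px
    px_y = lo[1] + (yy + 0.5) * px

    for t in range(params.n_frames):
        poly = pts[t]
        cols = (poly[:, 0] - lo[0]) / px - 0.5
        rows = (poly[:, 1] - lo[1]) / px - 0.5
        if (cols.min() < 0) or (rows.min() < 0) or (cols.max() > nx - 1) or (rows.max() > ny - 1):
            raise ValueError("cell leaves the field of view; increase margin")
        rr, cc = draw_polygon(rows, cols, shape=(ny, nx))
        mask = np.zeros((ny, nx), dtype=bool)
        mask[rr, cc] = True
        dist = ndimage.distance_transform_edt(mask, sampling=px)
        centroid = poly.mean(axis=0)
        theta = np.arctan2(px_y - centroid[1], px_x - centroid[0])
        cortex_val = intensities.value(theta, t)
        frame_img = np.where(
            mask, np.where(dist <= params.cortex_depth, cortex_val, intensities.interior_level), 0.0
        )
        if params.psf_sigma > 0:
            frame_img = ndimage.gaussian_filter(frame_img, sigma=params.psf_sigma / px)
        if params.noise_poisson_gain > 0:
            frame_img = rng.poisson(
                np.clip(frame_img, 0, None) * params.noise_poisson_gain
            ) / params.noise_poisson_gain
        if params.noise_gaussian_sigma > 0:
            frame_img = frame_img + rng.normal(0.0, params.noise_gaussian_sigma, frame_img.shape)
        for z in range(params.n_z):
            data[t, 0, z] = frame_img

    return TimeLapse(
        data=data,
        voxel_size_xy=px,
        voxel_size_z=params.voxel_size_z,
        frame_interval=params.frame_interval,
        channel_roles={"cell_marker": 0},
        origin=(float(lo[0]), float(lo[1])),
    )


def default_schedule(rng: np.random.Generator, params: SimulationParams) -> list[ProtrusionScript]:
    """Draw a realistic protrusion schedule: 2-3 events per movie, lifetimes
    spanning the transient/stable/long-life regimes (6-60 s)."""
    dt = params.frame_interval
    events = []
    cursor = 1  # first possible birth frame; events are sequential so their
    # high-curvature regions never merge on the boundary
    for _ in range(int(rng.integers(2, 4))):
        e = dt * int(rng.integers(1, 3))
        s = dt * int(rng.integers(1, 7))
        r = 2 * dt
        n_needed = int((e + s + r) / dt)
        if cursor + n_needed + 2 > params.n_frames:
            break
        events.append(
            ProtrusionScript(
                birth_frame=cursor,
                angle=None,
                amplitude=1.5,
                e_duration=e,
                s_duration=s,
                r_duration=r,
            )
        )
        cursor += n_needed + 2
    return events


def simulate_population(
    template: SimulationParams,
    n_cells: int,
    out_dir: str | Path,
    seed: int = 0,
    speeds: np.ndarray | None = None,
) -> pd.DataFrame:
    """Write ``n_cells`` rendered movies plus one ground-truth table.

    Per-cell seeds derive from the master seed, so the fixture directory is
    reproducible.  If ``speeds`` is given it overrides the template centroid
    speed per cell (useful for straddling the 0.1 µm/s motility cut); the
    table's ``expected_motile`` column marks cells the motility filter must
    keep.
    """
    from .io import write_timelapse

    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    master = np.random.default_rng(seed)
    rows = []
    for i in range(n_cells):
        cell_seed = int(master.integers(0, 2**31 - 1))
        params = dataclasses.replace(template, seed=cell_seed)
        if speeds is not None:
            params.centroid_speed = float(speeds[i])
        if not params.protrusion_schedule:
            params.protrusion_schedule = default_schedule(
                np.random.default_rng(cell_seed + 7), params
            )
        series, intensity, truth = simulate_cell(params)
        movie = render_movie(series, intensity, params)
        write_timelapse(out_dir / f"cell_{i:03d}.ome.tif", movie)
        for _, ev in truth.events.iterrows():
            rows.append({"cell_id": i, "seed": cell_seed, **ev.to_dict(),
                         "speed": params.centroid_speed,
                         "expected_motile": params.centroid_speed >= 0.1
                         and params.n_frames >= 10})
    table = pd.DataFrame(rows)
    table.to_csv(out_dir / "ground_truth.csv", index=False)
    cfg = dataclasses.asdict(template)
    cfg["protrusion_schedule"] = [dataclasses.asdict(e) for e in template.protrusion_schedule]
    cfg["n_cells"] = n_cells
    cfg["master_seed"] = seed
    with open(out_dir / "params.yaml", "w") as fh:
        yaml.safe_dump(json.loads(json.dumps(cfg)), fh)
    return table
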