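"""Cell segmentation, centroid tracking, subpixel boundary extraction and
motility classification.

Segmentation is a per-frame global Otsu threshold on the cell-marker
channel with 3-D connected-component labeling; objects are linked through
time by the minimum-displacement criterion on their geometric centroids.
The 2-D boundary of each object's max-projection is refined to subpixel
precision with an active contour ("snake") and resampled to exactly 100
evenly spaced points.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.optimize import linear_sum_assignment
from skimage import measure
from skimage.filters import threshold_otsu
from skimage.segmentation import active_contour

from .io import TimeLapse
from .simulate import _resample_closed

MOTILE_MIN_FRAMES = 10
MOTILE_MIN_SPEED = 0.1  # µm/s


@dataclass
class CellTrack:
    cell_id: int
    frames: list[int]
    centroid_path: np.ndarray          # (n, 2) µm, (x, y)
    masks: dict = field(default_factory=dict)   # frame -> (label_array, label_id)
    motility_class: str | None = None
    still: bool = False                # curation flag: non-activated round/static

    @property
    def n_frames(self) -> int:
        return len(self.frames)


def segment_frame(volume: np.ndarray, min_volume: int = 20,
                  min_separation: float = 4.0) -> np.ndarray:
    """Global-Otsu segmentation of one 3-D frame of the cell-marker channel.

    Components smaller than ``min_volume`` voxels are discarded.  Otsu
    always splits the histogram, so a background-only frame is recognized
    by requiring the foreground mean to clear the background by
    ``min_separation`` background standard deviations.  Raises on a
    constant volume, where the Otsu threshold is undefined.
    """
    volume = np.asarray(volume)
    if np.ptp(volume) == 0:
        raise ValueError("constant intensity volume: Otsu threshold undefined")
    thr = threshold_otsu(volume)
    binary = volume > thr
    bg = volume[~binary]
    if binary.any() and volume[binary].mean() - bg.mean() < min_separation * bg.std():
        return np.zeros_like(volume, dtype=np.int32)
    # cortically enriched markers can threshold as a shell; fill per plane
    for z in range(binary.shape[0]):
        binary[z] = ndimage.binary_fill_holes(binary[z])
    labels, n = ndimage.label(binary)
    if n and min_volume > 1:
        counts = np.bincount(labels.ravel())
        small = np.flatnonzero(counts < min_volume)
        labels[np.isin(labels, small[small > 0])] = 0
        labels, _ = ndimage.label(labels > 0)
    return labels


def _frame_objects(labels: np.ndarray, voxel_size_xy: float):
    """Centroids (x, y, µm, projected) and ids of labeled objects."""
    ids = np.unique(labels)
    ids = ids[ids > 0]
    centroids = []
    for i in ids:
        zz, yy, xx = np.nonzero(labels == i)
        centroids.append([xx.mean() * voxel_size_xy, yy.mean() * voxel_size_xy])
    return ids, np.array(centroids).reshape(-1, 2)


def track_objects(
    label_frames: list[np.ndarray],
    voxel_size_xy: float,
    frame_interval: float,
    max_link_distance: float = 10.0,
) -> list[CellTrack]:
    """Link objects frame-to-frame by minimum total centroid displacement.

    The per-frame-pair assignment minimizes the summed displacement
    (Hungarian algorithm); links longer than ``max_link_distance`` µm are
    severed, and unmatched objects start or end tracks.
    """
    tracks: list[CellTrack] = []
    open_tracks: dict[int, CellTrack] = {}   # current label id -> track
    next_cell_id = 0

    prev_ids, prev_cent = _frame_objects(label_frames[0], voxel_size_xy)
    for oid, c in zip(prev_ids, prev_cent):
        tr = CellTrack(cell_id=next_cell_id, frames=[0], centroid_path=c[None])
        tr.masks[0] = (label_frames[0], int(oid))
        open_tracks[int(oid)] = tr
        tracks.append(tr)
        next_cell_id += 1

    for t in range(1, len(label_frames)):
        ids, cent = _frame_objects(label_frames[t], voxel_size_xy)
        new_open: dict[int, CellTrack] = {}
        if len(ids) and len(prev_ids):
            cost = np.linalg.norm(prev_cent[:, None] - cent[None], axis=2)
            rows, cols = linear_sum_assignment(cost)
            matched_next = set()
            for r, c in zip(rows, cols):
                if cost[r, c] <= max_link_distance and int(prev_ids[r]) in open_tracks:
                    tr = open_tracks[int(prev_ids[r])]
                    tr.frames.append(t)
                    tr.centroid_path = np.vstack([tr.centroid_path, cent[c]])
                    tr.masks[t] = (label_frames[t], int(ids[c]))
                    new_open[int(ids[c])] = tr
                    matched_next.add(c)
        else:
            matched_next = set()
        for j, oid in enumerate(ids):
            if j not in matched_next:
                tr = CellTrack(cell_id=next_cell_id, frames=[t], centroid_path=cent[j][None])
                tr.masks[t] = (label_frames[t], int(oid))
                new_open[int(oid)] = tr
                tracks.append(tr)
                next_cell_id += 1
        open_tracks = new_open
        prev_ids, prev_cent = ids, cent

    for tr in tracks:
        tr.frame_interval = frame_interval
    return tracks


def extract_boundary(
    labels: np.ndarray,
    intensity_volume: np.ndarray,
    voxel_size_xy: float,
    label_id: int | None = None,
    origin: tuple = (0.0, 0.0),
    snake_alpha: float = 0.05,
    snake_beta: float = 2.0,
    snake_gamma: float = 0.01,
    snake_iterations: int = 30,
    refine: bool = True,
) -> np.ndarray:
    """Extract the 100-point subpixel boundary of one object.

    The object's max-projection contour is found at subpixel precision,
    refined against the projected intensity with an active contour, and
    resampled to 100 evenly spaced points with counterclockwise
    orientation.  Returns (100, 2) physical (x, y) coordinates in µm.

    Raises if the object touches the image border (such frames are excluded
    downstream as boundary-identification defects).
    """
    mask3d = (labels == label_id) if label_id is not None else (labels > 0)
    if not mask3d.any():
        raise ValueError("empty mask")
    proj = mask3d.max(axis=0)
    if (
        proj[0].any() or proj[-1].any() or proj[:, 0].any() or proj[:, -1].any()
    ):
        raise ValueError("object touches the image border")
    contours = measure.find_contours(proj.astype(float), 0.5)
    contour = max(contours, key=len)  # (row, col)

    if refine:
        img = intensity_volume.max(axis=0).astype(float)
        img = ndimage.gaussian_filter(img, 1.0)
        snake = active_contour(
            img,
            contour,
            alpha=snake_alpha,
            beta=snake_beta,
            gamma=snake_gamma,
            w_line=0.0,
            w_edge=1.0,
            max_num_iter=snake_iterations,
            boundary_condition="periodic",
        )
        # guard: a diverged snake is worse than the pixel contour
        if np.abs(snake - contour).max() < 3.0:
            contour = snake

    xy = np.column_stack([contour[:, 1], contour[:, 0]]) * voxel_size_xy
    xy = xy + np.array(origin) + 0.5 * voxel_size_xy
    # even chord spacing needs a smooth polyline: densify, filter the
    # pixel-level jag with a short periodic Gaussian, then resample
    dense = _resample_closed(xy, 400)
    dense = ndimage.gaussian_filter1d(dense, sigma=2.0, axis=0, mode="wrap")
    pts = _resample_closed(dense, 100)
    if _signed_area(pts) < 0:
        pts = pts[::-1]
    return pts


def _signed_area(points: np.ndarray) -> float:
    x, y = points[:, 0], points[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def classify_cell_motility(track: CellTrack, frame_interval: float | None = None) -> str:
    """Classify a track as still / jiggling / motile.

    Motile cells have at least 10 frames and average speed (path length /
    elapsed time) of at least 0.1 µm/s; active cells below that speed are
    jiggling; tracks carrying the curation ``still`` flag are still.
    """
    dt = frame_interval if frame_interval is not None else getattr(track, "frame_interval", None)
    if dt is None:
        raise ValueError("frame interval required")
    if track.still:
        track.motility_class = "still"
        return "still"
    if track.n_frames < 2:
        track.motility_class = "jiggling"
        return "jiggling"
    steps = np.linalg.norm(np.diff(track.centroid_path, axis=0), axis=1)
    elapsed = (track.frames[-1] - track.frames[0]) * dt
    speed = steps.sum() / elapsed if elapsed > 0 else 0.0
    if track.n_frames >= MOTILE_MIN_FRAMES and speed >= MOTILE_MIN_SPEED:
        cls = "motile"
    else:
        cls = "jiggling"
    track.motility_class = cls
    return cls


def motility_fractions(tracks: list[CellTrack]) -> dict:
    """Population fractions of still / jiggling / motile cells."""
    n = len(tracks)
    counts = {"still": 0, "jiggling": 0, "motile": 0}
    for tr in tracks:
        cls = tr.motility_class or classify_cell_motility(tr)
        counts[cls] += 1
    return {k: (v / n if n else 0.0) for k, v in counts.items()}
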