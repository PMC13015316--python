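"""Calibrated time-lapse I/O, frame registration, config and logging.

Stacks are held as T×C×Z×Y×X arrays with physical calibration (µm voxel
size, frame interval in seconds).  OME-TIFF is the on-disk format; all
tabular outputs elsewhere in the package are delimited text with a
``schema_version`` column.
"""

from __future__ import annotations

import logging
import time
from contextlib import contextmanager
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
import yaml

SCHEMA_VERSION = 1

log = logging.getLogger("protrudyn")


@dataclass
class TimeLapse:
    """A calibrated multi-channel 3D time-lapse stack (T, C, Z, Y, X)."""

    data: np.ndarray
    voxel_size_xy: float        # µm / pixel
    voxel_size_z: float         # µm / plane
    frame_interval: float       # s
    channel_roles: dict = field(default_factory=dict)
    origin: tuple = (0.0, 0.0)  # physical (x, y) of pixel (0, 0) corner, µm

    def __post_init__(self):
        if self.data.ndim != 5:
            raise ValueError("TimeLapse data must be 5-D (T, C, Z, Y, X)")
        if self.voxel_size_xy <= 0 or self.frame_interval <= 0:
            raise ValueError("voxel size and frame interval must be > 0")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    def channel(self, role: str) -> np.ndarray:
        """Return the (T, Z, Y, X) sub-stack for a named channel role."""
        return self.data[:, self.channel_roles[role]]


_AXES_ORDER = "TCZYX"


def write_timelapse(path: str | Path, stack: TimeLapse) -> None:
    """Write an OME-TIFF with voxel size and frame interval metadata."""
    meta = {
        "axes": _AXES_ORDER,
        "PhysicalSizeX": stack.voxel_size_xy,
        "PhysicalSizeY": stack.voxel_size_xy,
        "PhysicalSizeZ": stack.voxel_size_z,
        "PhysicalSizeXUnit": "µm",
        "PhysicalSizeYUnit": "µm",
        "PhysicalSizeZUnit": "µm",
        "TimeIncrement": stack.frame_interval,
        "TimeIncrementUnit": "s",
    }
    tifffile.imwrite(path, stack.data.astype(np.float32), ome=True, metadata=meta)


def read_timelapse(path: str | Path, overrides: dict | None = None) -> TimeLapse:
    """Read a TIFF/OME-TIFF and normalize axes to T, C, Z, Y, X.

    Calibration is taken from OME metadata when present; anything missing
    must be supplied in ``overrides`` (keys ``voxel_size_xy``,
    ``voxel_size_z``, ``frame_interval``, ``channel_roles``) or an error is
    raised.
    """
    overrides = overrides or {}
    with tifffile.TiffFile(path) as tif:
        series = tif.series[0]
        data = series.asarray()
        axes = series.axes.upper().replace("S", "C")
        # unlabeled axes: the leading one is time in a plain movie
        if "Q" in axes:
            axes = axes.replace("Q", "T" if "T" not in axes else "Z", 1)
            axes = axes.replace("Q", "Z")
        vsx = vsz = dt = None
        if tif.ome_metadata:
            import xml.etree.ElementTree as ET

            root = ET.fromstring(tif.ome_metadata)
            ns = {"ome": root.tag.split("}")[0].strip("{")}
            px = root.find(".//ome:Pixels", ns)
            if px is not None:
                vsx = px.get("PhysicalSizeX")
                vsz = px.get("PhysicalSizeZ")
                dt = px.get("TimeIncrement")
    for ax in axes:
        if ax not in _AXES_ORDER:
            raise ValueError(f"ambiguous axis {ax!r} in {path}")
    # insert missing axes as singletons, then order as TCZYX
    for ax in _AXES_ORDER:
        if ax not in axes:
            data = np.expand_dims(data, 0)
            axes = ax + axes
    data = np.moveaxis(data, [axes.index(a) for a in _AXES_ORDER], range(5))

    voxel_size_xy = overrides.get("voxel_size_xy", float(vsx) if vsx else None)
    voxel_size_z = overrides.get("voxel_size_z", float(vsz) if vsz else 1.0)
    frame_interval = overrides.get("frame_interval", float(dt) if dt else None)
    if voxel_size_xy is None:
        raise ValueError(f"{path}: voxel size missing; supply an override")
    if frame_interval is None:
        raise ValueError(f"{path}: frame interval missing; supply an override")
    roles = overrides.get("channel_roles", {"cell_marker": 0})
    return TimeLapse(
        data=data,
        voxel_size_xy=voxel_size_xy,
        voxel_size_z=voxel_size_z,
        frame_interval=frame_interval,
        channel_roles=roles,
    )


def register_frames(stack: TimeLapse, reference_channel: str = "matrix",
                    upsample_factor: int = 10):
    """Correlation-based frame registration against the first frame.

    Per-frame subpixel translations are estimated on the max-projection of
    the reference channel by upsampled phase cross-correlation, and the same
    shift is applied to every channel and z-plane.

    Returns (shifts, corrected) where ``shifts`` is (T, 2) in (y, x) pixels.
    """
    from scipy import ndimage
    from skimage.registration import phase_cross_correlation

    ref_stack = stack.channel(reference_channel)
    proj = ref_stack.max(axis=1)  # (T, Y, X)
    reference = proj[0]
    if np.ptp(reference) == 0:
        raise ValueError("reference channel is flat; registration undefined")

    n = stack.n_frames
    shifts = np.zeros((n, 2))
    corrected = stack.data.copy()
    for t in range(1, n):
        shift, _, _ = phase_cross_correlation(
            reference, proj[t], upsample_factor=upsample_factor, normalization=None
        )
        shifts[t] = shift
        for c in range(stack.data.shape[1]):
            for z in range(stack.data.shape[2]):
                corrected[t, c, z] = ndimage.shift(
                    stack.data[t, c, z], shift, order=1, mode="constant", cval=0.0
                )
    out = TimeLapse(
        data=corrected,
        voxel_size_xy=stack.voxel_size_xy,
        voxel_size_z=stack.voxel_size_z,
        frame_interval=stack.frame_interval,
        channel_roles=dict(stack.channel_roles),
        origin=stack.origin,
    )
    return shifts, out


def load_config(path: str | Path) -> dict:
    """Load a YAML key-value config (voxel_size, frame_interval, channel
    roles, analysis thresholds)."""
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def add_schema_version(df):
    """Stamp a tabular output with the writer schema version."""
    df = df.copy()
    df["schema_version"] = SCHEMA_VERSION
    return df


@contextmanager
def stage_timer(name: str):
    """Structured per-stage timing for pipeline logging."""
    t0 = time.perf_counter()
    log.info("stage %s started", name)
    try:
        yield
    finally:
        log.info("stage %s finished in %.2f s", name, time.perf_counter() - t0)
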