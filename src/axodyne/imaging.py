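"""Image-stack I/O, axon traces, and kymograph construction.

A kymograph re-plots a time-lapse movie of a traced axon as a 2D map with
time on the vertical axis (one row per frame) and arc length along the trace
on the horizontal axis.  Mitochondria moving along the axon appear as sloped
ridges whose slope is their velocity; stationary organelles appear as vertical
ridges.

Conventions: 0-based pixel indices; arc-length origin at the proximal
(cell-body) end of the trace, so anterograde motion is increasing arc length.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy.ndimage import map_coordinates

__all__ = [
    "ImageStack",
    "AxonTrace",
    "Kymograph",
    "read_stack",
    "write_stack",
    "read_trace",
    "write_trace",
    "build_kymograph",
    "write_kymograph",
    "read_kymograph",
]


@dataclass
class ImageStack:
    """A calibrated time-lapse stack: ``frames`` is (time, y, x)."""

    frames: np.ndarray
    frame_interval: float  # s
    pixel_size: float  # μm

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise ValueError("frames must be a (time, y, x) array with >= 1 frame")
        if self.frame_interval <= 0 or self.pixel_size <= 0:
            raise ValueError("frame_interval and pixel_size must be > 0")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def duration(self) -> float:
        """Elapsed time from first to last frame, (n-1)·Δt, in seconds."""
        return (self.n_frames - 1) * self.frame_interval


@dataclass
class AxonTrace:
    """Polyline trace of one axon, proximal (cell-body) vertex first."""

    polyline: np.ndarray  # (n, 2) float array of (x, y) pixel vertices
    pixel_size: float  # μm

    def __post_init__(self) -> None:
        self.polyline = np.asarray(self.polyline, dtype=float)
        if self.polyline.ndim != 2 or self.polyline.shape[0] < 2 or self.polyline.shape[1] != 2:
            raise ValueError("polyline must be an (n>=2, 2) array of (x, y) vertices")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")

    @property
    def arc_length_px(self) -> float:
        return float(np.sum(np.hypot(*np.diff(self.polyline, axis=0).T)))

    @property
    def calibrated_length(self) -> float:
        """Trace length in μm (arc length × pixel size)."""
        return self.arc_length_px * self.pixel_size


@dataclass
class Kymograph:
    """Time (rows) × arc-length (columns) intensity map of one axon."""

    matrix: np.ndarray
    bin_size: float  # μm per column
    frame_interval: float  # s per row

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix)
        if self.matrix.ndim != 2:
            raise ValueError("kymograph matrix must be 2D")
        if self.bin_size <= 0 or self.frame_interval <= 0:
            raise ValueError("bin_size and frame_interval must be > 0")

    @property
    def n_frames(self) -> int:
        return self.matrix.shape[0]

    @property
    def length_um(self) -> float:
        return self.matrix.shape[1] * self.bin_size


# ---------------------------------------------------------------------------
# TIFF I/O


def write_stack(stack: ImageStack, path: str | Path) -> None:
    """Write a stack as an uncompressed multi-page grayscale TIFF.

    Calibration is stored in a JSON sidecar ``<path>.json`` so a plain TIFF
    reader round-trips losslessly.
    """
    path = Path(path)
    tifffile.imwrite(path, stack.frames, photometric="minisblack")
    sidecar = {"frame_interval_s": stack.frame_interval, "pixel_size_um": stack.pixel_size}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar))


def read_stack(
    path: str | Path,
    frame_interval: float | None = None,
    pixel_size: float | None = None,
) -> ImageStack:
    """Read a multi-page TIFF; calibration from the sidecar unless overridden."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    frames = tifffile.imread(path)
    if frames.ndim == 2:
        frames = frames[None]
    if frames.ndim != 3:
        raise ValueError(f"expected a grayscale stack, got shape {frames.shape}")
    sidecar_path = path.with_suffix(path.suffix + ".json")
    meta = json.loads(sidecar_path.read_text()) if sidecar_path.exists() else {}
    frame_interval = frame_interval if frame_interval is not None else meta.get("frame_interval_s")
    pixel_size = pixel_size if pixel_size is not None else meta.get("pixel_size_um")
    if frame_interval is None or pixel_size is None:
        raise ValueError(
            f"no calibration for {path}: supply frame_interval/pixel_size or a sidecar JSON"
        )
    return ImageStack(frames, frame_interval=frame_interval, pixel_size=pixel_size)


def write_trace(trace: AxonTrace, path: str | Path) -> None:
    """Write an axon trace as a 2-column CSV (x_px, y_px), proximal end first."""
    pd.DataFrame(trace.polyline, columns=["x_px", "y_px"]).to_csv(path, index=False)


def read_trace(path: str | Path, pixel_size: float) -> AxonTrace:
    df = pd.read_csv(path)
    return AxonTrace(df[["x_px", "y_px"]].to_numpy(float), pixel_size=pixel_size)


# ---------------------------------------------------------------------------
# Kymograph construction


def _resample_polyline(polyline: np.ndarray, step_px: float) -> tuple[np.ndarray, np.ndarray]:
    """Resample a polyline at uniform arc-length steps.

    Returns (points, normals): bin-center coordinates (x, y) and the unit
    normal at each point.
    """
    seg = np.diff(polyline, axis=0)
    seg_len = np.hypot(seg[:, 0], seg[:, 1])
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    total = cum[-1]
    if total <= 0:
        raise ValueError("trace has zero length")
    n_bins = int(np.ceil(total / step_px))
    # bin centers in arc length
    s = (np.arange(n_bins) + 0.5) * (total / n_bins)
    x = np.interp(s, cum, polyline[:, 0])
    y = np.interp(s, cum, polyline[:, 1])
    # tangent per bin from which segment the bin center falls in
    idx = np.clip(np.searchsorted(cum, s, side="right") - 1, 0, len(seg) - 1)
    tx = seg[idx, 0] / seg_len[idx]
    ty = seg[idx, 1] / seg_len[idx]
    normals = np.stack([-ty, tx], axis=1)
    return np.stack([x, y], axis=1), normals


def build_kymograph(stack: ImageStack, trace: AxonTrace, band_halfwidth_px: int = 3) -> Kymograph:
    """Build a kymograph by maximum projection over a band normal to the trace.

    For every frame and every arc-length bin, the kymograph value is the
    maximum interpolated intensity over ``2*band_halfwidth_px + 1`` sample
    points spaced one pixel apart along the local normal.  The maximum (rather
    than the mean) preserves punctate mitochondrial signals at low SNR.

    The arc-length bin size equals the pixel size (no sub-pixel resampling).
    """
    if stack.n_frames < 2:
        raise ValueError("kymograph construction needs a stack with >= 2 frames")
    if band_halfwidth_px < 0:
        raise ValueError("band_halfwidth_px must be >= 0")
    points, normals = _resample_polyline(trace.polyline, step_px=1.0)
    h, w = stack.frames.shape[1:]
    if (
        points[:, 0].min() < -0.5
        or points[:, 0].max() > w - 0.5
        or points[:, 1].min() < -0.5
        or points[:, 1].max() > h - 0.5
    ):
        raise ValueError("trace lies outside the image bounds")
    offsets = np.arange(-band_halfwidth_px, band_halfwidth_px + 1)
    # sample coordinates: (n_bins, n_offsets, 2)
    coords = points[:, None, :] + offsets[None, :, None] * normals[:, None, :]
    ys = np.clip(coords[..., 1], 0, h - 1).ravel()
    xs = np.clip(coords[..., 0], 0, w - 1).ravel()
    n_bins, n_off = coords.shape[:2]
    rows = np.empty((stack.n_frames, n_bins), dtype=float)
    for t in range(stack.n_frames):
        vals = map_coordinates(stack.frames[t].astype(float), [ys, xs], order=1, mode="nearest")
        rows[t] = vals.reshape(n_bins, n_off).max(axis=1)
    return Kymograph(rows, bin_size=trace.pixel_size, frame_interval=stack.frame_interval)


def write_kymograph(kymo: Kymograph, path: str | Path) -> None:
    """Export a kymograph as TIFF plus JSON metadata sidecar."""
    path = Path(path)
    tifffile.imwrite(path, kymo.matrix.astype(np.float32), photometric="minisblack")
    meta = {"bin_size_um": kymo.bin_size, "frame_interval_s": kymo.frame_interval}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta))


def read_kymograph(path: str | Path) -> Kymograph:
    path = Path(path)
    matrix = tifffile.imread(path)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    return Kymograph(matrix, bin_size=meta["bin_size_um"], frame_interval=meta["frame_interval_s"])
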