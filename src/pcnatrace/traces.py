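"""Per-cell intensity and Sobel-gradient traces from image stacks and ROI masks.

The measurement per frame is: maximum-intensity projection over Z, then for
each cell (a labelled nuclear ROI) the mean projected intensity minus the
mean over a background region (the area between cells), and the mean
Sobel-gradient magnitude within the same ROI.  The Sobel magnitude is
computed on the full projected frame (reflection padding at the borders) and
only then masked, so that the mask edge itself contributes no artificial
gradients; no background is subtracted from Sobel values because a constant
offset has zero gradient.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

logger = logging.getLogger(__name__)

CHANNEL_NAMES = ("red", "green")

#: The background region is the complement of all cell masks eroded by this
#: many pixels, keeping it clear of nuclear edges.
BACKGROUND_EROSION_PX = 5


class EmptyROIError(ValueError):
    """The cell ROI contains no pixels."""


class EmptyBackgroundError(ValueError):
    """The background region contains no pixels."""


@dataclass(frozen=True)
class IntensityTrace:
    """Background-subtracted mean nuclear intensity of one cell/channel over time."""

    cell_id: int
    channel: str
    times_min: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.times_min, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.shape != v.shape or t.ndim != 1:
            raise ValueError("times and values must be matching 1-D arrays")
        if len(t) and np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(v)):
            raise ValueError("intensities must be finite")
        object.__setattr__(self, "times_min", t)
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class SobelTrace(IntensityTrace):
    """Mean Sobel-gradient magnitude within the nuclear ROI over time (>= 0)."""

    def __post_init__(self):
        super().__post_init__()
        if np.any(self.values < 0):
            raise ValueError("Sobel values must be >= 0")


def max_project(zstack) -> np.ndarray:
    """Per-pixel maximum across Z planes (a (Z, H, W) array or list of planes)."""
    planes = [np.asarray(p) for p in zstack]
    if len(planes) < 1:
        raise ValueError("need at least one Z plane")
    shape = planes[0].shape
    if any(p.shape != shape for p in planes):
        raise ValueError("Z planes must all have the same shape")
    return np.max(np.stack(planes), axis=0)


def roi_mean(image: np.ndarray, mask: np.ndarray, background_mask: np.ndarray) -> float:
    """Mean intensity under ``mask`` minus mean under ``background_mask``."""
    image = np.asarray(image, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    background_mask = np.asarray(background_mask, dtype=bool)
    if not mask.any():
        raise EmptyROIError("cell ROI is empty")
    if not background_mask.any():
        raise EmptyBackgroundError("background region is empty")
    if np.any(mask & background_mask):
        raise ValueError("background region overlaps the cell ROI")
    return float(image[mask].mean() - image[background_mask].mean())


def sobel_magnitude(image: np.ndarray) -> np.ndarray:
    """Sobel gradient magnitude sqrt(Gx^2 + Gy^2) of a 2-D image.

    Standard 3x3 Sobel kernels ([-1 0 1] differentiation smoothed by
    [1 2 1]), reflection padding at the borders.
    """
    image = np.asarray(image, dtype=float)
    gx = ndimage.sobel(image, axis=1, mode="reflect")
    gy = ndimage.sobel(image, axis=0, mode="reflect")
    return np.hypot(gx, gy)


def sobel_mean(image: np.ndarray, mask: np.ndarray) -> float:
    """Mean Sobel-gradient magnitude of ``image`` over the pixels of ``mask``."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise EmptyROIError("cell ROI is empty")
    return float(sobel_magnitude(image)[mask].mean())


def background_mask(labels: np.ndarray, erosion_px: int = BACKGROUND_EROSION_PX) -> np.ndarray:
    """Area between cells: complement of all labelled masks, eroded."""
    free = np.asarray(labels) == 0
    if erosion_px > 0:
        free = ndimage.binary_erosion(free, iterations=erosion_px)
    return free


def extract_traces(stack: np.ndarray, masks: np.ndarray,
                   frame_interval_min: float,
                   channel_names: tuple[str, ...] = CHANNEL_NAMES) -> pd.DataFrame:
    """Per-cell traces from a (T, Z, C, H, W) stack and (T, H, W) labelled masks.

    Returns a tidy frame with columns ``cell_id, channel, time_min,
    mean_intensity, sobel_mean``.  Cells may enter/leave the movie (their
    cycle ends); a frame missing a mask *between* a cell's first and last
    appearance is a tracking gap, recorded in ``df.attrs['gaps']`` and logged,
    never silently skipped.
    """
    stack = np.asarray(stack)
    masks = np.asarray(masks)
    if stack.ndim != 5:
        raise ValueError("stack must be (T, Z, C, H, W)")
    if masks.shape != (stack.shape[0],) + stack.shape[3:]:
        raise ValueError("masks must be (T, H, W) matching the stack")
    if len(channel_names) != stack.shape[2]:
        raise ValueError(f"got {stack.shape[2]} channels, {len(channel_names)} names")

    rows = []
    seen_frames: dict[int, list[int]] = {}
    for f in range(stack.shape[0]):
        t = f * frame_interval_min
        labels = masks[f]
        bg = background_mask(labels)
        if not bg.any():
            raise EmptyBackgroundError(f"frame {f}: no background area between cells")
        cells = np.unique(labels)
        cells = cells[cells != 0]
        for c, name in enumerate(channel_names):
            proj = max_project(stack[f, :, c])
            mag = sobel_magnitude(proj)
            bg_mean = float(proj[bg].mean())
            for cid in cells:
                roi = labels == cid
                rows.append({
                    "cell_id": int(cid),
                    "channel": name,
                    "time_min": t,
                    "mean_intensity": float(proj[roi].mean()) - bg_mean,
                    "sobel_mean": float(mag[roi].mean()),
                })
        for cid in cells:
            seen_frames.setdefault(int(cid), []).append(f)

    df = pd.DataFrame(rows, columns=["cell_id", "channel", "time_min",
                                     "mean_intensity", "sobel_mean"])
    gaps = []
    for cid, frames in sorted(seen_frames.items()):
        expected = set(range(frames[0], frames[-1] + 1))
        missing = sorted(expected - set(frames))
        if missing:
            gaps.append({"cell_id": cid, "missing_frames": missing})
            logger.warning("cell %d: mask missing in frames %s", cid, missing)
    df.attrs["gaps"] = gaps
    return df


def get_trace(df: pd.DataFrame, cell_id: int, channel: str,
              value: str = "sobel_mean") -> tuple[np.ndarray, np.ndarray]:
    """(times, values) for one cell/channel from a tidy trace frame."""
    channels = df["channel"].unique()
    if channel not in channels:
        raise KeyError(f"channel {channel!r} not present (have {sorted(channels)})")
    sub = df[(df["cell_id"] == cell_id) & (df["channel"] == channel)]
    if sub.empty:
        raise KeyError(f"no trace for cell {cell_id}, channel {channel!r}")
    sub = sub.sort_values("time_min")
    return sub["time_min"].to_numpy(float), sub[value].to_numpy(float)
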