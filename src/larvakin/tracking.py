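"""Single-larva centroid tracking on background-subtracted frame stacks.

Converts a directory (or in-memory stack) of grayscale frames into a
well-centered millimetre trajectory: estimate a static background (median
over a frame subsample), threshold the background-subtracted image at a
robust multiple of its noise spread, keep connected components above a
minimum area inside the well, and take the intensity-weighted centroid of
the largest.  Short detection gaps are linearly interpolated and flagged;
long gaps are flagged missing for downstream exclusion.

The default polarity assumes a dark larva on a bright, transilluminated
background; ``polarity="bright"`` inverts it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from skimage import measure

from .kinematics import FLAG_INTERPOLATED, FLAG_MISSING, FLAG_OK, Trajectory
from .synthetic import FrameStack

__all__ = [
    "TrackingConfig",
    "estimate_background",
    "detect_centroid",
    "track",
    "load_frames",
]


@dataclass(frozen=True)
class TrackingConfig:
    """Knobs of the detection stage.

    ``threshold_sd`` multiplies the robust spread (1.4826 x MAD) of the
    difference image; blob pixels are outliers by construction, so MAD
    reflects the noise floor.  ``min_abs_threshold`` guards the noiseless
    limit where MAD collapses to zero.
    """

    background_method: str = "median_stack"  # median_stack | first_frame | provided
    threshold_sd: float = 5.0
    min_blob_area: int = 4
    max_gap_fill: int = 3
    polarity: str = "dark"  # dark | bright larva
    min_abs_threshold: float = 2.0

    def __post_init__(self) -> None:
        if self.threshold_sd <= 0:
            raise ValueError("threshold_sd must be positive")
        if self.min_blob_area < 1:
            raise ValueError("min_blob_area must be >= 1")
        if self.max_gap_fill < 0:
            raise ValueError("max_gap_fill must be >= 0")
        if self.background_method not in ("median_stack", "first_frame", "provided"):
            raise ValueError("unknown background_method")
        if self.polarity not in ("dark", "bright"):
            raise ValueError("polarity must be 'dark' or 'bright'")


def estimate_background(
    frames: np.ndarray,
    method: str = "median_stack",
    max_sample: int = 200,
) -> np.ndarray:
    """Per-pixel background estimate over a uniform subsample of frames.

    The median is robust as long as the moving larva occupies any given
    pixel in fewer than half of the sampled frames.
    """
    frames = np.asarray(frames)
    if frames.ndim != 3 or frames.shape[0] < 1:
        raise ValueError("need a non-empty (n, h, w) frame stack")
    if method == "first_frame":
        return frames[0].astype(float)
    if method != "median_stack":
        raise ValueError(f"unknown background method {method!r}")
    n = frames.shape[0]
    idx = np.unique(np.linspace(0, n - 1, min(n, max_sample)).astype(int))
    return np.median(frames[idx].astype(float), axis=0)


def detect_centroid(
    frame: np.ndarray,
    background: np.ndarray,
    config: TrackingConfig = TrackingConfig(),
    well_mask: np.ndarray | None = None,
) -> tuple[float, float] | None:
    """Intensity-weighted centroid (col, row) of the largest blob, or None.

    The difference image is signed by polarity (background - frame for a
    dark larva), thresholded at ``threshold_sd`` robust spreads, and
    restricted to ``well_mask`` when given.
    """
    frame = np.asarray(frame, dtype=float)
    background = np.asarray(background, dtype=float)
    if frame.shape != background.shape:
        raise ValueError("frame and background shapes differ")
    diff = background - frame if config.polarity == "dark" else frame - background
    med = np.median(diff)
    spread = 1.4826 * np.median(np.abs(diff - med))
    thr = max(config.threshold_sd * spread, config.min_abs_threshold)
    mask = diff > thr
    if well_mask is not None:
        mask &= well_mask
    if not mask.any():
        return None
    labels = measure.label(mask)
    props = measure.regionprops(labels)
    props = [p for p in props if p.area >= config.min_blob_area]
    if not props:
        return None
    best = max(props, key=lambda p: p.area)
    component = labels == best.label
    weights = np.where(component, np.maximum(diff, 0.0), 0.0)
    total = weights.sum()
    rows, cols = np.nonzero(component)
    w = weights[rows, cols]
    return float(np.sum(cols * w) / total), float(np.sum(rows * w) / total)


def track(
    stack: FrameStack,
    config: TrackingConfig = TrackingConfig(),
    background: np.ndarray | None = None,
) -> Trajectory:
    """Track the larva through a frame stack into a mm trajectory.

    Gaps of at most ``max_gap_fill`` frames between detections are filled
    by linear interpolation and flagged; longer (or edge) gaps are flagged
    missing.  Raises when more than half of the frames lack a detection
    (unusable recording).
    """
    frames = stack.frames
    n = frames.shape[0]
    if n == 0:
        raise ValueError("empty frame stack")
    if config.background_method == "provided":
        if background is None:
            raise ValueError("background_method='provided' needs a background")
        bg = np.asarray(background, dtype=float)
    else:
        bg = estimate_background(frames, config.background_method)

    h, w = frames.shape[1:]
    yy, xx = np.mgrid[0:h, 0:w]
    cx, cy = stack.well_center_px
    well_mask = (xx - cx) ** 2 + (yy - cy) ** 2 <= (stack.well_radius_px + 2) ** 2

    cols = np.full(n, np.nan)
    rows = np.full(n, np.nan)
    for i in range(n):
        hit = detect_centroid(frames[i], bg, config, well_mask)
        if hit is not None:
            cols[i], rows[i] = hit

    detected = np.isfinite(cols)
    if detected.sum() < n / 2:
        raise ValueError("more than 50% of frames have no detection")

    flags = np.full(n, FLAG_OK, dtype=object)
    missing_runs = _nan_runs(detected)
    for s, e in missing_runs:
        interior = s > 0 and e < n
        if interior and (e - s) <= config.max_gap_fill:
            t = np.arange(s, e)
            cols[s:e] = np.interp(t, [s - 1, e], [cols[s - 1], cols[e]])
            rows[s:e] = np.interp(t, [s - 1, e], [rows[s - 1], rows[e]])
            flags[s:e] = FLAG_INTERPOLATED
        else:
            flags[s:e] = FLAG_MISSING

    x_mm = (cols - cx) * stack.mm_per_px
    y_mm = (cy - rows) * stack.mm_per_px
    # keep missing samples finite but flagged
    bad = flags == FLAG_MISSING
    x_mm[bad] = 0.0
    y_mm[bad] = 0.0
    return Trajectory(frame_rate=stack.frame_rate_hz, x=x_mm, y=y_mm, flags=flags)


def _nan_runs(detected: np.ndarray) -> list[tuple[int, int]]:
    gaps = []
    n = detected.size
    i = 0
    while i < n:
        if not detected[i]:
            j = i
            while j < n and not detected[j]:
                j += 1
            gaps.append((i, j))
            i = j
        else:
            i += 1
    return gaps


def load_frames(directory) -> FrameStack:
    """Read a zero-padded PNG/TIFF frame directory plus its JSON sidecar."""
    import imageio.v3 as iio

    directory = Path(directory)
    meta = json.loads((directory / "stack.json").read_text())
    files = sorted(
        p for p in directory.iterdir() if p.suffix.lower() in (".png", ".tif", ".tiff")
    )
    if not files:
        raise ValueError(f"no frames found in {directory}")
    frames = np.stack([iio.imread(p) for p in files])
    return FrameStack(
        frames=frames,
        frame_rate_hz=float(meta["frame_rate_hz"]),
        mm_per_px=float(meta["mm_per_px"]),
        well_center_px=tuple(meta["well_center_px"]),
        well_radius_px=float(meta["well_radius_px"]),
    )
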