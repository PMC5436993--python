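"""Video I/O, calibration, rigid registration and stable-window selection.

Handheld vital microscopy (incident dark field / sidestream dark field)
produces short grayscale clips of the sublingual mucosa in which
hemoglobin-filled vessels appear dark on a bright background.  Everything
downstream (quality grading, vessel segmentation, velocimetry) operates on a
:class:`FrameStack`: a calibrated, temporally ordered stack of single-channel
frames together with the stable analysis window selected from it.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile
from skimage.registration import phase_cross_correlation

logger = logging.getLogger(__name__)

__all__ = [
    "Calibration",
    "FrameStack",
    "DriftTrace",
    "NoStableWindowError",
    "load_stack",
    "estimate_drift",
    "select_stable_window",
    "CALIBRATION_PRESETS",
]


class NoStableWindowError(RuntimeError):
    """No contiguous sequence satisfied the stability thresholds.

    ``longest_run`` carries the length (frames) of the longest run found, so
    callers can report how far the clip was from being analyzable.
    """

    def __init__(self, message: str, longest_run: int):
        super().__init__(message)
        self.longest_run = longest_run


@dataclass(frozen=True)
class Calibration:
    """Spatial and temporal calibration of a clip.

    Parameters
    ----------
    pixel_pitch_um : float
        Physical size of one pixel (micrometres per pixel).
    frame_rate : float
        Acquisition rate in frames per second.
    fov_area_mm2 : float
        Area of the imaged field of view in square millimetres.

    Notes
    -----
    Two named presets are shipped for the CytoCam acquisition geometry and
    must be selected explicitly (``Calibration.preset(...)``): the vendor's
    printed pixel size of 2.8 um/px, and the pitch implied by a
    2208 x 1648 px sensor covering 1.78 mm^2 (~0.6995 um/px).  The two are
    mutually inconsistent, so no silent default is offered; the choice is
    logged.
    """

    pixel_pitch_um: float
    frame_rate: float
    fov_area_mm2: float

    def __post_init__(self):
        for name in ("pixel_pitch_um", "frame_rate", "fov_area_mm2"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"Calibration.{name} must be strictly positive, got {v!r}")

    @classmethod
    def preset(cls, name: str, frame_rate: float = 25.0) -> "Calibration":
        try:
            pitch, fov = CALIBRATION_PRESETS[name]
        except KeyError:
            raise KeyError(
                f"unknown calibration preset {name!r}; available: {sorted(CALIBRATION_PRESETS)}"
            ) from None
        logger.info("using calibration preset %r: %.4f um/px, %.2f mm^2", name, pitch, fov)
        return cls(pixel_pitch_um=pitch, frame_rate=frame_rate, fov_area_mm2=fov)

    @classmethod
    def from_mapping(cls, mapping: dict) -> "Calibration":
        """Build from a config mapping: either ``{'preset': name}`` or explicit
        ``{pixel_pitch_um, frame_rate, fov_area_mm2}``."""
        if "preset" in mapping:
            return cls.preset(mapping["preset"], frame_rate=mapping.get("frame_rate", 25.0))
        return cls(
            pixel_pitch_um=float(mapping["pixel_pitch_um"]),
            frame_rate=float(mapping["frame_rate"]),
            fov_area_mm2=float(mapping["fov_area_mm2"]),
        )

    def check_frame_shape(self, shape: tuple[int, int]) -> None:
        """Warn when the declared FOV disagrees >5% with shape x pitch^2."""
        h, w = shape
        implied = h * w * (self.pixel_pitch_um / 1000.0) ** 2
        if abs(implied - self.fov_area_mm2) > 0.05 * self.fov_area_mm2:
            warnings.warn(
                f"declared FOV area {self.fov_area_mm2:.3f} mm^2 differs from "
                f"frame-implied {implied:.3f} mm^2 by more than 5%",
                stacklevel=2,
            )


# (pixel_pitch_um, fov_area_mm2) pairs; see Calibration docstring.
CALIBRATION_PRESETS: dict[str, tuple[float, float]] = {
    "cytocam-printed": (2.8, 1.78),
    "cytocam-fov-derived": (0.6995, 1.78),
}


@dataclass
class FrameStack:
    """A calibrated sequence of single-channel frames — the unit of analysis."""

    frames: np.ndarray  # (n_frames, H, W), float32
    calibration: Calibration
    source_id: str = ""
    stable_window: tuple[int, int] | None = None  # half-open [start, end)
    intensity_range: tuple[float, float] = (0.0, 255.0)

    def __post_init__(self):
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError(f"frames must be a (n, H, W) array, got shape {self.frames.shape}")
        if self.frames.shape[0] < 2:
            raise ValueError("a FrameStack needs at least 2 frames")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("frame intensities must be finite")
        if self.stable_window is not None:
            self._validate_window(self.stable_window)

    def _validate_window(self, window: tuple[int, int]) -> None:
        s, e = window
        if not (0 <= s < e <= self.n_frames) or e - s < 2:
            raise ValueError(f"stable_window {window} invalid for {self.n_frames} frames")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.calibration.frame_rate

    def window_frames(self) -> np.ndarray:
        """Frames restricted to the stable window (whole stack if unset)."""
        if self.stable_window is None:
            return self.frames
        s, e = self.stable_window
        return self.frames[s:e]

    def median_image(self) -> np.ndarray:
        """Temporal median over the stable window.

        The median suppresses the moving erythrocyte texture while keeping
        the static vessel walls — the detection image for segmentation.
        """
        return np.median(self.window_frames(), axis=0)


@dataclass
class DriftTrace:
    """Per-frame rigid displacement (row, col) relative to the previous frame,
    plus the cumulative displacement relative to the first frame."""

    steps: np.ndarray  # (n_frames, 2); steps[0] == (0, 0)
    cumulative: np.ndarray  # (n_frames, 2)

    def __post_init__(self):
        self.steps = np.asarray(self.steps, dtype=float)
        self.cumulative = np.asarray(self.cumulative, dtype=float)
        if self.steps.shape != self.cumulative.shape or self.steps.ndim != 2:
            raise ValueError("steps and cumulative must be matching (n, 2) arrays")
        if np.any(self.steps[0] != 0):
            raise ValueError("first drift entry must be (0, 0)")

    @property
    def n_frames(self) -> int:
        return self.steps.shape[0]

    @property
    def step_magnitude(self) -> np.ndarray:
        return np.hypot(self.steps[:, 0], self.steps[:, 1])


def _to_single_channel(frames: np.ndarray) -> np.ndarray:
    """Collapse colour video to one channel.

    The green channel is preferred because vessel contrast in incident dark
    field imaging comes from hemoglobin absorption, which peaks in green.
    """
    if frames.ndim == 3:
        return frames
    if frames.ndim == 4 and frames.shape[-1] in (3, 4):
        return frames[..., 1]
    raise ValueError(f"cannot interpret frame array of shape {frames.shape} as video")


def load_stack(path: str | Path, calibration: Calibration, source_id: str | None = None) -> FrameStack:
    """Read a multi-page TIFF or uncompressed AVI into a :class:`FrameStack`.

    Colour input is reduced to its green channel.  Raises ``IOError`` for an
    unreadable file and ``ValueError`` when fewer than two frames are found.
    """
    path = Path(path)
    try:
        if path.suffix.lower() in (".tif", ".tiff"):
            frames = tifffile.imread(path)
        else:
            frames = iio.imread(path)
    except (OSError, ValueError) as exc:
        raise IOError(f"could not read video file {path}: {exc}") from exc
    frames = np.asarray(frames)
    if frames.size == 0:
        raise IOError(f"could not read video file {path}: no image data found")
    if frames.ndim == 2:
        raise ValueError(f"{path} contains a single frame; a video stack is required")
    frames = _to_single_channel(frames)
    if frames.dtype == np.uint8:
        irange = (0.0, 255.0)
    elif frames.dtype == np.uint16:
        irange = (0.0, 65535.0)
    else:
        irange = (float(frames.min()), float(frames.max()))
    stack = FrameStack(
        frames=frames.astype(np.float32),
        calibration=calibration,
        source_id=source_id or path.name,
        intensity_range=irange,
    )
    calibration.check_frame_shape(stack.frame_shape)
    logger.info("loaded %s: %d frames of %s (%.1f s)", stack.source_id, stack.n_frames,
                stack.frame_shape, stack.duration_s)
    return stack


def estimate_drift(stack: FrameStack) -> DriftTrace:
    """Estimate rigid translation between successive frames.

    Integer-pixel translation only, by phase cross-correlation of each frame
    against its predecessor.  Constant (zero-variance) frames produce a zero
    step with a logged warning instead of an error.
    """
    n = stack.n_frames
    steps = np.zeros((n, 2))
    prev = stack.frames[0]
    for i in range(1, n):
        cur = stack.frames[i]
        if prev.std() == 0 or cur.std() == 0:
            logger.warning("%s: zero-variance frame at index %d; assuming zero drift",
                           stack.source_id, i)
            steps[i] = (0.0, 0.0)
        else:
            # phase normalization weights all spatial frequencies equally, so
            # the static scene dominates over locally moving cell texture
            shift, _, _ = phase_cross_correlation(prev, cur, upsample_factor=1,
                                                  normalization="phase")
            # shift registers cur onto prev; displacement of cur is its negative
            steps[i] = -shift
        prev = cur
    return DriftTrace(steps=steps, cumulative=np.cumsum(steps, axis=0))


def select_stable_window(
    stack: FrameStack,
    trace: DriftTrace,
    min_frames: int = 150,
    max_step_px: float = 2.0,
    max_span_px: float = 10.0,
) -> tuple[int, int]:
    """Select the longest contiguous run of frames with bounded motion.

    A window ``[s, e)`` qualifies when every per-frame step strictly inside it
    is at most ``max_step_px`` and every frame stays within ``max_span_px`` of
    the window's first frame (cumulative excursion).  The longest qualifying
    window of at least ``min_frames`` frames wins; ties break to the earliest
    start.  The chosen window is stored on ``stack.stable_window``.

    Raises :class:`NoStableWindowError` (carrying the longest run found) when
    no window qualifies.
    """
    if trace.n_frames != stack.n_frames:
        raise ValueError("drift trace does not match stack")
    n = stack.n_frames
    mags = trace.step_magnitude
    cum = trace.cumulative

    # phase 1: maximal runs in which every interior per-frame step is small
    breaks = [0] + [i for i in range(1, n) if mags[i] > max_step_px] + [n]
    runs = [(breaks[k], breaks[k + 1]) for k in range(len(breaks) - 1)]

    # phase 2: within each run, longest window with bounded cumulative excursion
    best: tuple[int, int] | None = None
    longest_run = 1
    for a, b in runs:
        for s in range(a, b):
            if best is not None and b - s <= best[1] - best[0]:
                break  # no longer window can start here
            e = s + 1
            while e < b and np.hypot(*(cum[e] - cum[s])) <= max_span_px:
                e += 1
            length = e - s
            longest_run = max(longest_run, length)
            if length >= min_frames and (best is None or length > best[1] - best[0]):
                best = (s, e)

    if best is None:
        raise NoStableWindowError(
            f"{stack.source_id}: no stable sequence of >= {min_frames} frames "
            f"(longest stable run: {longest_run} frames)",
            longest_run=longest_run,
        )
    stack.stable_window = best
    logger.info("%s: stable window %s (%d frames)", stack.source_id, best, best[1] - best[0])
    return best
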