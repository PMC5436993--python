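"""Six-trait video quality grading (Massey score) and the analysis gate.

Clips are graded on six traits — illumination, duration, focus, content,
stability, pressure — each taking a value in {0, 1, 10} (0 good, 1 marginal,
10 unacceptable).  A clip is analyzable when the total is below 10, i.e. no
single trait is unacceptable.

Four traits are scored automatically from image statistics; the automated
thresholds are documented proxies, not a re-derivation of the published
per-trait rubric.  *Content* (vessel loops, stasis patterns) and *pressure*
(probe-pressure artifacts) require human judgment: they default to 0 with a
logged notice and can be overridden.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .framestack import DriftTrace, FrameStack

logger = logging.getLogger(__name__)

TRAITS = ("illumination", "duration", "focus", "content", "stability", "pressure")
ALLOWED_VALUES = (0, 1, 10)

__all__ = ["MasseyScore", "MasseyThresholds", "score_clip", "TRAITS"]


@dataclass(frozen=True)
class MasseyScore:
    illumination: int
    duration: int
    focus: int
    content: int
    stability: int
    pressure: int

    def __post_init__(self):
        for t in TRAITS:
            v = getattr(self, t)
            if v not in ALLOWED_VALUES:
                raise ValueError(f"Massey trait {t!r} must be one of {ALLOWED_VALUES}, got {v!r}")

    @property
    def total(self) -> int:
        return sum(getattr(self, t) for t in TRAITS)

    @property
    def passed(self) -> bool:
        """Analyzable iff total < 10 (no trait unacceptable)."""
        return self.total < 10

    def as_dict(self) -> dict[str, int]:
        return {t: getattr(self, t) for t in TRAITS}


@dataclass(frozen=True)
class MasseyThresholds:
    """Config for the automated trait proxies.

    clip_frac_good / clip_frac_marginal
        Fraction of pixels clipped at the intensity extremes: below the first
        scores 0, below the second 1, else 10.
    focus_good / focus_marginal
        High-frequency energy fraction of the median image (variance of the
        residual after 2 px Gaussian smoothing over total variance).  Sharp
        capillary imagery sits well above 0.02; defocused clips fall below.
    step_good_px / step_marginal_px
        95th-percentile per-frame drift step for stability 0 / 1.
    duration_good / duration_marginal
        Minimum stable-window length in frames for duration 0 / 1 (150 frames
        = 6 s at 25 fps; half that is marginal).
    """

    clip_frac_good: float = 0.01
    clip_frac_marginal: float = 0.05
    focus_good: float = 0.02
    focus_marginal: float = 0.005
    step_good_px: float = 2.0
    step_marginal_px: float = 4.0
    duration_good: int = 150
    duration_marginal: int = 75


def _grade(value: float, good: float, marginal: float, larger_is_better: bool) -> int:
    if larger_is_better:
        return 0 if value >= good else (1 if value >= marginal else 10)
    return 0 if value <= good else (1 if value <= marginal else 10)


def _illumination_trait(stack: FrameStack, thr: MasseyThresholds) -> int:
    lo, hi = stack.intensity_range
    span = hi - lo
    img = stack.median_image()
    clipped = np.mean((img <= lo + 0.005 * span) | (img >= hi - 0.005 * span))
    return _grade(clipped, thr.clip_frac_good, thr.clip_frac_marginal, larger_is_better=False)


def _focus_trait(stack: FrameStack, thr: MasseyThresholds) -> int:
    img = stack.median_image().astype(float)
    total_var = img.var()
    if total_var == 0:
        return 10
    residual = img - ndimage.gaussian_filter(img, 2.0)
    return _grade(residual.var() / total_var, thr.focus_good, thr.focus_marginal,
                  larger_is_better=True)


def _stability_trait(trace: DriftTrace, thr: MasseyThresholds) -> int:
    step95 = float(np.percentile(trace.step_magnitude[1:], 95)) if trace.n_frames > 1 else 0.0
    return _grade(step95, thr.step_good_px, thr.step_marginal_px, larger_is_better=False)


def _duration_trait(stack: FrameStack, thr: MasseyThresholds) -> int:
    if stack.stable_window is None:
        return 10
    s, e = stack.stable_window
    return _grade(e - s, thr.duration_good, thr.duration_marginal, larger_is_better=True)


def score_clip(
    stack: FrameStack,
    trace: DriftTrace,
    manual: dict[str, int] | None = None,
    thresholds: MasseyThresholds | None = None,
) -> MasseyScore:
    """Grade a clip; manual per-trait overrides always win.

    ``stack.stable_window`` should be set before scoring (the duration trait
    grades the stable-window length); an unset window grades duration as 10.
    """
    thr = thresholds or MasseyThresholds()
    manual = dict(manual or {})
    unknown = set(manual) - set(TRAITS)
    if unknown:
        raise ValueError(f"unknown Massey traits in overrides: {sorted(unknown)}")
    for t, v in manual.items():
        if v not in ALLOWED_VALUES:
            raise ValueError(f"Massey override {t}={v!r} not in {ALLOWED_VALUES}")

    values = {
        "illumination": _illumination_trait(stack, thr),
        "duration": _duration_trait(stack, thr),
        "focus": _focus_trait(stack, thr),
        "stability": _stability_trait(trace, thr),
        "content": 0,
        "pressure": 0,
    }
    for t in ("content", "pressure"):
        if t not in manual:
            logger.info("%s: Massey trait %r not machine-assessed; defaulting to 0",
                        stack.source_id, t)
    values.update(manual)
    score = MasseyScore(**values)
    logger.info("%s: Massey total %d (%s)", stack.source_id, score.total,
                "pass" if score.passed else "FAIL")
    return score
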