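"""End-to-end per-clip analysis: load -> register -> gate -> segment -> flow.

`analyze_clip` composes the full automated pathway and returns a
:class:`ClipResult` carrying the measurements, the quality score and
provenance (config hash, software version).  Clips failing the quality gate
keep their Massey score but have all measurements withheld — a gated clip
is not a clip with zero density.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

from . import __version__
from .config import RunConfig
from .framestack import FrameStack, estimate_drift, load_stack, select_stable_window
from .quality import MasseyScore, MasseyThresholds, score_clip
from .velocimetry import SpeedField, compute_apsi, compute_speed_field
from .vessels import VesselMap, VesselnessParams, compute_vesselness, segment_vessels

logger = logging.getLogger(__name__)

__all__ = ["ClipResult", "analyze_clip", "analyze_stack"]


@dataclass
class ClipResult:
    source_id: str
    massey: MasseyScore
    gated: bool  # True when the quality gate withheld analysis
    tvd: float | None
    apsi: float | None
    n_segments: int | None
    n_capillaries: int | None
    stable_window: tuple[int, int] | None
    config_hash: str
    version: str = __version__
    vessel_map: VesselMap | None = None
    speed_field: SpeedField | None = None

    def row(self) -> dict:
        """Flat record for CSV/JSON output."""
        return {
            "source_id": self.source_id,
            "massey_total": self.massey.total,
            "quality_passed": not self.gated,
            "tvd_auto": self.tvd,
            "apsi": self.apsi,
            "n_segments": self.n_segments,
            "n_capillaries": self.n_capillaries,
            "window_start": None if self.stable_window is None else self.stable_window[0],
            "window_end": None if self.stable_window is None else self.stable_window[1],
            "config_hash": self.config_hash,
            "version": self.version,
        }


def analyze_stack(stack: FrameStack, config: RunConfig, keep_fields: bool = False) -> ClipResult:
    """Run the automated pathway on an already-loaded stack."""
    trace = estimate_drift(stack)
    window = None
    try:
        window = select_stable_window(
            stack, trace,
            min_frames=config.window.min_frames,
            max_step_px=config.window.max_step_px,
            max_span_px=config.window.max_span_px,
        )
    except RuntimeError as exc:
        logger.warning("%s: %s", stack.source_id, exc)

    q = config.quality
    massey = score_clip(
        stack, trace, manual=q.overrides,
        thresholds=MasseyThresholds(
            clip_frac_good=q.clip_frac_good, clip_frac_marginal=q.clip_frac_marginal,
            focus_good=q.focus_good, focus_marginal=q.focus_marginal,
            step_good_px=q.step_good_px, step_marginal_px=q.step_marginal_px,
            duration_good=q.duration_good, duration_marginal=q.duration_marginal,
        ),
    )
    chash = config.content_hash()
    if not massey.passed or window is None:
        logger.warning("%s: quality gate failed (Massey %d); measurements withheld",
                       stack.source_id, massey.total)
        return ClipResult(
            source_id=stack.source_id, massey=massey, gated=True,
            tvd=None, apsi=None, n_segments=None, n_capillaries=None,
            stable_window=window, config_hash=chash,
        )

    vcfg = config.vessels
    params = VesselnessParams.for_calibration(
        stack.calibration,
        min_diameter_um=vcfg.min_diameter_um,
        max_diameter_um=vcfg.max_diameter_um,
        n_scales=vcfg.n_scales,
        beta=vcfg.beta,
        c=vcfg.c,
    )
    median = stack.median_image()
    vesselness = compute_vesselness(median, params)
    vmap = segment_vessels(
        median, vesselness, params, stack.calibration,
        threshold=vcfg.threshold, min_length_um=vcfg.min_length_um,
        min_area_px=vcfg.min_area_px,
    )
    field = compute_speed_field(
        stack, vmap,
        kernel_sigma_px=config.velocimetry.kernel_sigma_px,
        perfusion_factor=config.velocimetry.perfusion_factor,
    )
    return ClipResult(
        source_id=stack.source_id, massey=massey, gated=False,
        tvd=vmap.tvd, apsi=compute_apsi(field),
        n_segments=len(vmap.segments), n_capillaries=len(vmap.capillaries),
        stable_window=stack.stable_window, config_hash=chash,
        vessel_map=vmap if keep_fields else None,
        speed_field=field if keep_fields else None,
    )


def analyze_clip(path: str | Path, config: RunConfig, keep_fields: bool = False) -> ClipResult:
    """Load a video file and run the automated pathway on it."""
    stack = load_stack(path, config.calibration)
    return analyze_stack(stack, config, keep_fields=keep_fields)
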