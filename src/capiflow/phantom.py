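"""Synthetic vital-microscopy phantom videos with exact ground truth.

The generator renders dark tubular vessels on a bright mucosal background,
the way hemoglobin-filled microvessels appear under incident dark field
illumination.  Each vessel is a smooth polyline tube with a Gaussian
cross-profile; erythrocyte texture is modelled as a one-dimensional smooth
random pattern advected along the centerline at a constant (plug-flow)
velocity.  Illumination gradients, additive Gaussian noise and global rigid
drift complete the scene.

Ground truth (per-vessel centerline, arc length, width, velocity, capillary
flag, and the implied total vessel density) is returned alongside the pixel
data, so every analysis stage — segmentation, density, velocimetry, speed
indicator — can be validated without clinical video material.

Plug flow is a deliberate simplification: the analysis pathway measures
centerline texture motion, for which a parabolic profile adds nothing but
confounds the imposed-velocity oracle.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .framestack import Calibration, FrameStack

logger = logging.getLogger(__name__)

__all__ = ["VesselPhantom", "PhantomSpec", "PhantomTruth", "generate_phantom", "random_spec"]


@dataclass(frozen=True)
class VesselPhantom:
    """One synthetic vessel: control polyline, calibre, flow and texture.

    ``control_points`` are (row, col) pixel coordinates interpolated with a
    Catmull-Rom-like smooth curve.  ``width_um`` is the full width at half
    maximum of the Gaussian absorption profile.  ``velocity_um_s`` is the
    plug-flow advection speed of the texture (0 = stasis).
    ``texture_wavelength_um`` sets the correlation length of the random
    erythrocyte pattern; ``contrast`` the modulation depth of that pattern
    relative to the vessel's mean absorption.
    """

    control_points: tuple[tuple[float, float], ...]
    width_um: float
    velocity_um_s: float
    texture_wavelength_um: float = 60.0
    contrast: float = 0.5
    depth: float = 80.0  # absorption dip in intensity units at background level

    def __post_init__(self):
        if self.width_um <= 0:
            raise ValueError("vessel width must be > 0")
        if self.velocity_um_s < 0:
            raise ValueError("vessel velocity must be >= 0")
        if len(self.control_points) < 2:
            raise ValueError("a vessel needs at least 2 control points")


@dataclass(frozen=True)
class PhantomSpec:
    """Complete description of a phantom clip; ``seed`` fixes every pixel."""

    frame_shape: tuple[int, int]
    n_frames: int
    calibration: Calibration
    vessels: tuple[VesselPhantom, ...]
    background: float = 200.0
    illumination_gradient: float = 0.1  # fractional left-right shading
    background_texture_sd: float = 3.0  # static mucosal tissue texture
    noise_sd: float = 2.0
    drift_px_per_frame: tuple[float, float] = (0.0, 0.0)
    seed: int = 0


@dataclass
class PhantomTruth:
    """Exact per-vessel ground truth and the implied TVD."""

    centerlines: list[np.ndarray]  # dense (n, 2) (row, col) polylines
    lengths_um: np.ndarray
    widths_um: np.ndarray
    velocities_um_s: np.ndarray
    is_capillary: np.ndarray
    tvd: float  # mm capillary length per mm^2
    seed: int

    def to_json(self, path: str | Path) -> None:
        payload = {
            "seed": self.seed,
            "tvd_mm_per_mm2": self.tvd,
            "vessels": [
                {
                    "length_um": float(l),
                    "width_um": float(w),
                    "velocity_um_s": float(v),
                    "is_capillary": bool(c),
                }
                for l, w, v, c in zip(
                    self.lengths_um, self.widths_um, self.velocities_um_s, self.is_capillary
                )
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def _smooth_polyline(control: np.ndarray, step_px: float = 0.5) -> np.ndarray:
    """Densely resample a control polyline with a smooth (quadratic) blend."""
    control = np.asarray(control, dtype=float)
    if len(control) == 2:
        dense = control
    else:
        # Catmull-Rom through the control points
        pts = np.vstack([control[0], control, control[-1]])
        segs = []
        for i in range(1, len(pts) - 2):
            p0, p1, p2, p3 = pts[i - 1], pts[i], pts[i + 1], pts[i + 2]
            t = np.linspace(0, 1, 20, endpoint=False)[:, None]
            segs.append(
                0.5
                * (
                    2 * p1
                    + (-p0 + p2) * t
                    + (2 * p0 - 5 * p1 + 4 * p2 - p3) * t**2
                    + (-p0 + 3 * p1 - 3 * p2 + p3) * t**3
                )
            )
        segs.append(pts[-2][None])
        dense = np.vstack(segs)
    # re-parameterize to constant arc-length step
    d = np.hypot(*np.diff(dense, axis=0).T)
    s = np.concatenate([[0.0], np.cumsum(d)])
    n = max(int(s[-1] / step_px), 2)
    u = np.linspace(0, s[-1], n)
    return np.column_stack([np.interp(u, s, dense[:, 0]), np.interp(u, s, dense[:, 1])])


def _arc_length_px(points: np.ndarray) -> float:
    return float(np.sum(np.hypot(*np.diff(points, axis=0).T)))


def _render_vessel_geometry(poly: np.ndarray, shape: tuple[int, int], sigma_px: float):
    """Per-pixel absorption profile and arc-length coordinate of one tube.

    Returns (pixel_rows, pixel_cols, profile, arc_px) for pixels within
    3 sigma of the centerline.  The arc coordinate of a pixel is that of its
    nearest centerline sample, obtained through the Euclidean distance
    transform of the rasterized centerline.
    """
    canvas = np.full(shape, -1.0)
    arc = np.concatenate([[0.0], np.cumsum(np.hypot(*np.diff(poly, axis=0).T))])
    rr = np.clip(np.round(poly[:, 0]).astype(int), 0, shape[0] - 1)
    cc = np.clip(np.round(poly[:, 1]).astype(int), 0, shape[1] - 1)
    canvas[rr, cc] = arc
    dist, (ir, ic) = ndimage.distance_transform_edt(canvas < 0, return_indices=True)
    within = dist <= 3.0 * sigma_px
    pr, pc = np.nonzero(within)
    profile = np.exp(-dist[pr, pc] ** 2 / (2.0 * sigma_px**2))
    arc_px = canvas[ir[pr, pc], ic[pr, pc]]
    return pr, pc, profile, arc_px


def generate_phantom(spec: PhantomSpec) -> tuple[FrameStack, PhantomTruth]:
    """Render a phantom clip and its exact ground truth.

    Raises ``ValueError`` (listing the offenders) when any vessel control
    point falls outside the frame.
    """
    h, w = spec.frame_shape
    bad = [
        i
        for i, v in enumerate(spec.vessels)
        if any(not (0 <= r < h and 0 <= c < w) for r, c in v.control_points)
    ]
    if bad:
        raise ValueError(f"vessels outside frame bounds: {bad}")

    rng = np.random.default_rng(spec.seed)
    pitch = spec.calibration.pixel_pitch_um
    fps = spec.calibration.frame_rate

    # static scene + per-vessel advected texture
    cols = np.arange(w) / max(w - 1, 1)
    illum = 1.0 + spec.illumination_gradient * (cols - 0.5)
    base = spec.background * np.ones((h, w)) * illum[None, :]
    if spec.background_texture_sd > 0:
        # static smooth tissue texture: anchors rigid registration the way
        # out-of-focus mucosal structure does in real recordings
        tex2d = ndimage.gaussian_filter(rng.standard_normal((h, w)), 3.0)
        base = base + spec.background_texture_sd * tex2d / max(tex2d.std(), 1e-9)

    vessel_render = []
    centerlines, lengths, widths, velocities = [], [], [], []
    for v in spec.vessels:
        poly = _smooth_polyline(np.asarray(v.control_points))
        sigma_px = (v.width_um / pitch) / 2.355  # FWHM -> sigma
        pr, pc, profile, arc_px = _render_vessel_geometry(poly, (h, w), sigma_px)
        delta_px = v.velocity_um_s / (fps * pitch)  # plug-flow phase step
        lam_px = max(v.texture_wavelength_um / pitch, 2.0)
        arc_len = _arc_length_px(poly)
        # smooth random 1-D texture long enough for the whole clip
        tex_len = int(arc_len + delta_px * spec.n_frames + 8 * lam_px) + 4
        tex = rng.standard_normal(tex_len)
        tex = ndimage.gaussian_filter1d(tex, lam_px / 4.0, mode="wrap")
        sd = tex.std()
        tex = np.clip(tex / sd, -2.0, 2.0) if sd > 0 else tex
        vessel_render.append((v, pr, pc, profile, arc_px, tex, delta_px))
        centerlines.append(poly)
        lengths.append(arc_len * pitch)
        widths.append(v.width_um)
        velocities.append(v.velocity_um_s)

    frames = np.empty((spec.n_frames, h, w), dtype=np.float32)
    drift = np.asarray(spec.drift_px_per_frame, dtype=float)
    for t in range(spec.n_frames):
        # absorption composes multiplicatively where vessels overlap
        transmission = np.ones((h, w))
        for v, pr, pc, profile, arc_px, tex, delta_px in vessel_render:
            # texture phase advances by delta_px per frame along the centerline
            idx = arc_px + delta_px * (spec.n_frames - 1 - t)
            g = np.interp(idx, np.arange(len(tex)), tex)
            absorb = np.clip(
                (v.depth / spec.background) * profile * (1.0 + v.contrast * g), 0.0, 0.95
            )
            transmission[pr, pc] *= 1.0 - absorb
        frame = base * transmission
        if np.any(drift):
            cum = np.round(drift * t).astype(int)
            frame = np.roll(frame, shift=(cum[0], cum[1]), axis=(0, 1))
        if spec.noise_sd > 0:
            frame = frame + rng.normal(0.0, spec.noise_sd, size=(h, w))
        frames[t] = np.clip(frame, 0.0, 255.0)

    lengths = np.asarray(lengths)
    widths = np.asarray(widths)
    velocities = np.asarray(velocities)
    is_cap = widths <= 25.0
    tvd = float(np.sum(lengths[is_cap]) / 1000.0 / spec.calibration.fov_area_mm2)
    truth = PhantomTruth(
        centerlines=centerlines,
        lengths_um=lengths,
        widths_um=widths,
        velocities_um_s=velocities,
        is_capillary=is_cap,
        tvd=tvd,
        seed=spec.seed,
    )
    stack = FrameStack(
        frames=frames,
        calibration=spec.calibration,
        source_id=f"phantom-seed{spec.seed}",
        intensity_range=(0.0, 255.0),
    )
    logger.info("phantom seed %d: %d vessels, truth TVD %.2f mm/mm^2",
                spec.seed, len(spec.vessels), tvd)
    return stack, truth


def random_spec(
    seed: int,
    frame_shape: tuple[int, int] = (476, 476),
    n_frames: int = 170,
    calibration: Calibration | None = None,
    target_tvd: float = 15.0,
    width_range_um: tuple[float, float] = (5.0, 12.0),
    velocity_range_um_s: tuple[float, float] = (100.0, 500.0),
    noise_sd: float = 2.0,
    stasis_fraction: float = 0.0,
    margin_px: int = 6,
) -> PhantomSpec:
    """Random capillary-bed phantom reaching a target true TVD.

    Vessels are gently curved tracks spanning the frame with random
    orientation; they are added until the summed capillary centerline length
    implies ``target_tvd``.  Defaults emulate the measurement regime of
    healthy sublingual mucosa: TVD in the mid-teens mm/mm^2, capillary
    calibres 5-12 um, red-cell velocities of order 10^2 um/s, at the
    printed CytoCam pitch of 2.8 um/px.  ``stasis_fraction`` freezes that
    fraction of vessels (velocity 0) to exercise the perfusion rule.
    """
    rng = np.random.default_rng(seed)
    cal = calibration or Calibration(
        pixel_pitch_um=2.8,
        frame_rate=25.0,
        fov_area_mm2=frame_shape[0] * frame_shape[1] * (2.8 / 1000.0) ** 2,
    )
    h, w = frame_shape
    pitch = cal.pixel_pitch_um
    target_len_um = target_tvd * cal.fov_area_mm2 * 1000.0
    # capillaries cross each other in projection but do not co-run: reject
    # candidates that hug an existing centerline for more than a short stretch
    min_sep_px = 1.75 * width_range_um[1] / pitch

    vessels: list[VesselPhantom] = []
    existing_pts: list[np.ndarray] = []
    tree: cKDTree | None = None
    total_um = 0.0
    attempts = 0
    while total_um < target_len_um and attempts < 20000:
        attempts += 1
        # a gently curved track between two random points on the frame border
        theta = rng.uniform(0, np.pi)
        direction = np.array([np.sin(theta), np.cos(theta)])
        normal = np.array([-direction[1], direction[0]])
        center = np.array([rng.uniform(margin_px, h - margin_px),
                           rng.uniform(margin_px, w - margin_px)])
        # slab intersection of the track with the margin-inset frame rectangle
        t_lo, t_hi = -np.inf, np.inf
        for axis, (lo, hi) in enumerate([(margin_px, h - 1 - margin_px),
                                         (margin_px, w - 1 - margin_px)]):
            if abs(direction[axis]) > 1e-9:
                t1 = (lo - center[axis]) / direction[axis]
                t2 = (hi - center[axis]) / direction[axis]
                t_lo = max(t_lo, min(t1, t2))
                t_hi = min(t_hi, max(t1, t2))
        # a random sub-interval of the crossing chord: short capillary
        # stretches fill the gaps that full-span tracks cannot
        min_len_t = 160.0 / pitch
        if t_hi - t_lo > min_len_t:
            span = rng.uniform(min_len_t, t_hi - t_lo)
            t0 = rng.uniform(t_lo, t_hi - span)
            t_lo, t_hi = t0, t0 + span
        n_ctrl = 5
        ts = np.linspace(t_lo, t_hi, n_ctrl)
        bow = rng.uniform(-0.08, 0.08) * (t_hi - t_lo)
        ctrl_pts = center + np.outer(ts, direction) \
            + np.outer(bow * np.sin(np.linspace(0, np.pi, n_ctrl)), normal)
        ctrl_pts[:, 0] = np.clip(ctrl_pts[:, 0], margin_px, h - 1 - margin_px)
        ctrl_pts[:, 1] = np.clip(ctrl_pts[:, 1], margin_px, w - 1 - margin_px)
        poly = _smooth_polyline(ctrl_pts)
        length_px = _arc_length_px(poly)
        if length_px * pitch < 150.0:  # too short to be a useful track
            continue
        if tree is not None:
            d, _ = tree.query(poly[::2], k=1)
            near = (d < min_sep_px).mean()
            if near > 0.08:  # allows transversal crossings, forbids co-running
                continue
        width = rng.uniform(*width_range_um)
        flowing = rng.random() >= stasis_fraction
        velocity = rng.uniform(*velocity_range_um_s) if flowing else 0.0
        vessels.append(
            VesselPhantom(
                control_points=tuple((float(r), float(c)) for r, c in ctrl_pts),
                width_um=width, velocity_um_s=velocity,
            )
        )
        existing_pts.append(poly)
        tree = cKDTree(np.vstack(existing_pts)[::2])
        total_um += length_px * pitch

    return PhantomSpec(
        frame_shape=frame_shape,
        n_frames=n_frames,
        calibration=cal,
        vessels=tuple(vessels),
        noise_sd=noise_sd,
        seed=seed,
    )
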