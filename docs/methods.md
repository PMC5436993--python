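# Methods

This note documents the models and numerical choices behind capiflow's
analysis pathway, what the synthetic phantom does and does not emulate, and
the known limitations. Units: lengths in µm (densities mm/mm²), velocities
in µm/s, time in frames or seconds; pixel quantities are stated as px.

## Frame stacks, registration and the stable window

The unit of analysis is a calibrated grayscale frame stack. Calibration
(pixel pitch µm/px, frame rate 1/s, FOV area mm²) must be supplied
explicitly: the two published descriptions of the CytoCam geometry are
mutually inconsistent (a printed pixel size of 2.8 µm/px versus
2208 × 1648 px covering 1.78 mm², which implies ≈0.70 µm/px), so the package
ships both as named presets and refuses to guess. Colour input is reduced to
the green channel, where hemoglobin absorption gives vessel contrast.

Inter-frame motion is estimated as integer-pixel rigid translation by phase
cross-correlation of successive frames. Phase normalization is deliberate:
it weights all spatial frequencies equally, so the static tissue scene
dominates the estimate rather than the high-energy moving cell texture
inside vessels (with plain correlation, a single strongly perfused venule
can masquerade as global drift). Sub-pixel registration and rotation are out
of scope — translation at 1 px resolution is sufficient for window selection
and kymograph stability and keeps the estimator exact on synthetic data.

"Stable sequence" is operationalized with two thresholds: every per-frame
step ≤ 2 px and every frame within 10 px of the window's first frame. The
longest contiguous window of ≥ 150 frames (6 s at 25 fps) satisfying both is
selected, ties to the earliest start. All three numbers are configuration.

## Quality gating

Clips are graded on the six-trait 0/1/10 scheme (illumination, duration,
focus, content, stability, pressure); totals ≥ 10 fail and measurements are
withheld — a gated clip is reported as unanalyzable, never as zero density.
Four traits are scored by automated proxies: histogram clipping fraction
(1% / 5% breakpoints) for illumination, stable-window length (150 / 75
frames) for duration, high-frequency energy fraction of the median image
(0.02 / 0.005) for focus, and the 95th-percentile drift step (2 / 4 px) for
stability. The focus and illumination breakpoints were fixed by inspecting
sharp versus artificially degraded phantom clips; they are proxies for an
operator's judgment, not a re-derivation of the published rubric. Content
and pressure require semantic judgment (vessel loops, compression-induced
stasis patterns); they default to 0 with a logged notice and accept manual
overrides, which always win.

## Vessel detection and total vessel density

Detection runs on the temporal median image of the stable window, which
suppresses moving erythrocyte texture while preserving vessel walls.

**Vesselness.** Standard multiscale ridge filtering: per scale σ, Gaussian-
derivative Hessian with second derivatives multiplied by σ² (γ = 2), eigen-
values ordered |λ₁| ≤ |λ₂|, response
exp(−R_B²/2β²)·(1 − exp(−S²/2c²)) where λ₂ > 0 (dark-on-bright), zero
otherwise; maximum over scales. Defaults: β = 0.5; c = half the maximum
Hessian norm per scale (auto); eight geometrically spaced scales such that
2σ·pitch spans 4–30 µm — the upper end deliberately overshoots the 25 µm
capillary cut so that small venules are detected and then *rejected by
calibre* instead of silently missed. The image mean is subtracted before
filtering because truncated derivative kernels do not sum exactly to zero;
this makes the response invariant to intensity offsets by construction.

**Mask.** Hysteresis thresholding (high 0.15 on the [0, 1] response, low =
half of that, connected): the filter response dips where vessels cross (the
local structure is blob-like, R_B → 1) and at vessel ends, and hysteresis
retains those connected low-response stretches without admitting background.
Small objects (< 30 px) are removed and small holes (≤ 64 px) filled.

**Centerlines.** The mask is skeletonized and split into branches at
junction pixels (≥ 3 skeleton neighbours). Each branch end adjacent to a
junction cluster is extended to the cluster centroid — a crossing point lies
on the centerline of *both* vessels through it, so every arm legitimately
reaches the crossing center; free ends are prolonged along their local
direction while the mask continues, compensating the skeleton's end
retraction. Branch length is measured by chords spanning every 5th pixel of
the chain (plus the endpoint): per-pixel chain metrics (1/√2 steps)
overestimate digitized oblique lines by up to ~8%, whereas 5-px chords are
near-exact on straight and gently curved digital lines and under-read
realistic curvature by far less than 1%. Branches shorter than 10 µm are
dropped as spurs.

**Calibre and the capillary cut.** Per-point diameter is a full-width-at-
half-maximum measure on the detection image itself: vessel depth is the
intensity deficit against a 25 px Gaussian-smoothed background estimate, and
the diameter at a centerline point is twice its distance to the boundary of
the region where depth exceeds half the segment's median centerline depth.
This keeps calibre independent of the vesselness threshold, whose response
lobes are wider than the vessel. A segment is not a capillary when the 90th
percentile of its per-point diameters exceeds 25 µm; the high quantile
(rather than the maximum) prevents a single junction bulge from
reclassifying a long capillary, while a genuinely wide vessel exceeds the
cut along most of its course. The background smoothing biases FWHM slightly
upward for vessels wider than ~25 µm (they leak into their own background
estimate); this only widens the margin by which they are excluded.

TVD is the summed capillary centerline length (mm) divided by the FOV area
(mm²). Non-capillary segments are reported but excluded from the sum.

## Velocimetry

**Kymographs.** Intensity is sampled along a supplied centerline at 1 px
arc-length steps (bilinear interpolation) for every frame of the stable
window; rows are positions, columns frames. The manual protocol takes 3–5
user-identified contrast lines and averages their slopes; the automatic mode
estimates the dominant stripe orientation from the mean structure tensor of
the row-mean-removed diagram. Velocity = slope × pitch × frame rate, signed
along the path direction.

Two numerical points in the automatic mode. First, a kymograph whose moving
residual is tiny relative to its static profile (< 20% RMS) is classified as
zero flow — the content is a frozen pattern plus sensor noise, and noise
alone would otherwise masquerade as vertical (i.e. infinitely fast)
structure, because bilinear sampling correlates noise along the position
axis but not along time. Second, steep stripes displace the texture by more
than its correlation length between frames, which biases raw gradient
orientations low; the estimator therefore iterates three times, re-smoothing
along the position axis at 1.6 × the current slope estimate (clipped to
[2, 16] px; smoothing columns identically leaves the stripe slope
unchanged). The 1.6 factor was calibrated once on synthetic kymographs with
imposed slopes and then frozen; with it, imposed velocities of 50–500 µm/s
are recovered within a few percent. Slopes beyond a quarter of the path
length per frame — or near-vertical dominant orientations — raise an
aliasing error instead of returning a number, mirroring the physical limit
of a 25 fps acquisition.

**Speed indicator and APSI.** At every capillary centerline point p the
temporal series I_t(p) over the stable window is reduced to
mean_t |I_{t+1}(p) − I_t(p)|, normalized by the temporal dynamic range
(95th − 5th percentile, floored at the median background range as a noise
epsilon), then Gaussian-smoothed along the centerline (σ = 2 px). The
indicator is dimensionless, invariant to affine intensity rescaling of the
clip, and strictly increasing with sub-aliasing plug-flow speed; it is *not*
an absolute velocity, and its numeric scale is implementation-specific —
only within-pipeline comparisons (between conditions, between clips) are
meaningful. A point is flagged perfused when its raw temporal activity
exceeds twice the median activity of off-vessel background pixels (sampled
outside the 5-px-dilated mask). APSI is the mean indicator over perfused
points; with no perfused point it is reported as missing, never zero. The
exact indicator formula and the perfusion rule are this package's
constructions for an operation that is usually described only as a
Gaussian-kernel "speed image" over intensity variation.

## The phantom generator

The generator renders what the analysis pathway assumes: dark tubes with
Gaussian cross-profiles (width = FWHM) on a bright background, composed
multiplicatively where vessels overlap (absorption), plus a lateral
illumination gradient (±5%), a static smooth tissue texture (SD 3 intensity
units — it also anchors rigid registration, as out-of-focus mucosal
structure does in real recordings), additive Gaussian noise (SD 2 on a
background of 200), and optional integer global drift. Flow is plug flow: a
1-D smooth random texture (correlation set by a 60 µm wavelength parameter,
±50% modulation of the vessel's absorption) advected along the centerline at
exactly v/(frame rate × pitch) px/frame. A single seeded generator fixes
every pixel; identical seeds give bit-identical clips.

`random_spec` builds capillary-bed phantoms in the regime the acquisition
geometry observes in healthy mucosa: 476 × 476 px at the printed 2.8 µm/px
(FOV ≈ 1.78 mm²), 170 frames, target TVD reached by adding gently curved
tracks of calibre 5–12 µm and velocity 100–500 µm/s until the summed
centerline length matches. Candidate tracks are rejected when more than 8%
of their course runs within 1.75 × the maximum calibre of an existing
centerline: capillaries in projection cross transversally but do not co-run,
and two co-running tubes are unresolvable in principle (one skeleton line
for two true centerlines). A stasis fraction freezes that share of vessels
to exercise the perfusion rule.

What the phantom does **not** emulate: optics (point-spread function,
scattering, depth-of-field), parabolic flow profiles, discrete
erythrocyte/plasma-gap granularity, leukocytes, vessel tortuosity in depth,
focal drift, or compression artifacts. Passing phantom tests therefore
demonstrates that the algorithms recover what they model — imposed geometry
and advection under noise, shading and drift — not that clinical accuracy
equals phantom accuracy.

Problem sizes used in tests and the acceptance script (10 phantoms at
476², 30 at 300² for APSI, four velocities plus a refusal case for
velocimetry, 200 statistical replicates) were chosen to give stable
estimates on a single CPU; recovery results are insensitive to further
enlargement.

## Challenge statistics

Per-subject condition comparisons (native / acetylcholine / nitroglycerin)
use classic fixed-effects one-way ANOVA; `anova_from_summary` reconstructs
the identical F and p from printed per-group (n, mean, SEM) via
n·SEM² = group variance, and agrees with the raw-data ANOVA to 1e-10 when
fed exact summaries. Pairwise comparisons default to Welch's t
(rank-sum switchable — the choice of two-sample test is not fixed by the
protocol being modeled) with Benjamini–Hochberg step-up adjustment.
Mann–Whitney U uses exact enumeration for combined n ≤ 12 without ties and
the tie-corrected normal approximation otherwise. Bland–Altman agreement is
reported as bias (mean difference), precision (SD of differences — the pair
of published values is consistent with either the SD or the
limits-of-agreement convention, so both are reported) and limits of
agreement (bias ± 1.96 SD), with differences oriented automated − manual.
Topical dose arithmetic is amount (µmol) = volume × concentration /
dilution.

One power-related caveat documented here because it is easy to misread:
resampling synthetic per-subject tables from published group summaries
reproduces a study's *expected* significance pattern, but the probability of
reproducing the full pattern in any single replicate is bounded by the
per-comparison power implied by those summaries — for moderate effects
(e.g. a ~3-SE difference) that is ~80% per comparison, and the joint
probability across several required comparisons is substantially lower. A
single published realization of such a pattern is therefore entirely
consistent with replicate-level reproduction rates near 50–65%.

## Limitations

* Calibre estimates inherit the background-estimation bias described above
  and are FWHM-based; vessels near the 25 µm cut can be classified
  differently than a wall-to-wall manual measurement would.
* The speed indicator saturates as per-frame displacement approaches the
  texture correlation length; above the aliasing bound the velocimeter
  refuses rather than extrapolates. A 25 fps acquisition cannot measure
  fast venular flow reliably; higher frame rates relax both limits.
* Automated Massey traits are proxies; clips failing on content or pressure
  can only be caught by the manual overrides.
* TVD recovery was validated to within 5% on phantoms in the 14–21 mm/mm²
  regime; far denser beds increase crossing and merging losses.
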