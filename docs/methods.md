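# Methods

`dermoct` reimplements a multifunctional OCT analysis of murine skin as a
deterministic, fully testable pipeline.  Because no raw imaging data are
distributed, every analysis stage is validated against a synthetic phantom
generator whose ground truth is known exactly.  This note records the
models, the defaults that matter, and the design choices that were
genuinely open.

## Phantom model

**Speckle.**  Structural and angiographic volumes carry fully developed
speckle: each voxel's complex field is a circularly symmetric complex
Gaussian scaled by the layer's mean backscatter, so pre-log intensity is
exponentially distributed with mean equal to the reflectivity.  Repeats
share one scatterer realization and differ only by additive complex noise
(variance `intensity_noise`, default 1e-3), which is what makes
inter-repeat correlation meaningful for angiography.  No attenuation,
shadowing or beam-profile modeling is attempted; the phantom is a
statistics generator, not an optics simulator.

**Geometry.**  Defaults mirror the emulated acquisition: 500 A-lines per
B-scan, 500 B-scans, 5 repeats over 5.16 x 6.14 mm (lateral pitches ~10.3
and ~12.3 um), 1300 nm center wavelength, 100 kHz A-line rate.  The axial
pitch (optical path per pixel) defaults to 5 um; it is not stated by the
emulated system and is freely configurable.  Interfaces are specified in
physical um and placed at axial pixel `depth * n / pitch` with tissue
refractive index n = 1.376.

**Elastic wave.**  The OCE phantom encodes a windowed sine tone burst
(`n_pushes` cycles at 1, 5 or 10 kHz; 1 cycle maps to the single-push
scheme, 3 to the push train) propagating laterally from the field center
at a single group velocity; displacement is exactly zero before the
arrival time `|x - x0| / c` and decays as `exp(-alpha |x - x0|)`
(default 0.2 /mm).  Dispersion is not simulated: the analysis estimates
group velocity only, so a non-dispersive phantom is the appropriate
truth model.  Displacement enters the wrapped phase as
`4 pi n u / lambda` plus Gaussian phase noise, default SD 0.05 rad —
deliberately far above the sub-nanometer stability of a real
phase-locked system, so recovery margins are conservative.

**Vessels.**  Lumens are circular tubes around polyline centerlines.  A
fraction `decorrelation` of the complex amplitude power inside the lumen
is redrawn independently per repeat (1 = fully developed flow); static
tissue keeps its realization.  The phantom does not emulate bulk motion,
projection artifacts, or multiple scattering tails below vessels.

**Cohorts.**  Long-format (animal, group, site, day, metric, value)
records are drawn as `mean + sd * (sqrt(rho) b_animal + sqrt(1-rho) e)`,
with a standard-normal per-animal effect shared across that animal's
records and intra-animal correlation rho = 0.5.  The marginal SD of each
cell equals the stated SD, so between-group contrasts are calibrated,
while repeated measures on one animal are positively correlated, so
paired tests gain power — the structure the real study relies on.  The
default four-group design anchors the day-28 velocity contrast at
1.6 +/- 0.3 vs 1.2 +/- 0.2 m/s; all other cell values are plausible
synthetic trajectories of matching magnitude, not measured data.

What passing phantom tests shows: the estimators are unbiased and precise
under speckle statistics, additive noise and known truth.  What it does
not show: robustness to motion artifact, depth-dependent attenuation,
heterogeneous anatomy or operator variation in real recordings.

## Thickness

Pipeline order: average the repeats (linear mean), trim 100 edge frames
and 50 edge A-lines per side (with the full acquisition this retains
300 x 400 x 5 = 600 000 A-lines per position), detect surfaces, exclude
pigmented A-lines, convert with `(bottom - top) * pitch / 1.376`.

Surface detection thresholds the axially smoothed (3-px moving mean)
linear intensity at background mean + k SD, with the background taken
from the shallowest 20 axial rows and k = 4 by default; the emulated
protocol states thresholding but no constant.  The top surface is the
first supra-threshold sample, the bottom the last, and both are
median-filtered laterally over 5 A-lines to suppress single-speckle
dropouts.  Because the threshold is background-relative, thickness is
invariant to global intensity scaling.

Pigment exclusion is automated: A-lines whose mean in-tissue linear
intensity falls below a percentile (default 5th) of the lateral
distribution are dropped.  A percentile cut excludes that fraction by
construction even on clean data; on phantoms with a 12 dB patch it
removes essentially the whole patch at low false-exclusion cost.  The
emulated protocol used manual confirmation, which is not reproducible —
this replacement is recorded in every run record.

The "top and bottom surfaces" are implemented as generic two-interface
tracking (air-tissue and the deepest supra-threshold interface); with a
single-slab phantom the distinction between epidermis-only and full-skin
readings does not arise, and the conversion sentence ("mean difference
between the two surfaces") is what the code implements.

## Elastography

Displacement is recovered by temporal phase differencing: consecutive
phase differences are wrapped back into (-pi, pi] (temporal unwrapping
only; per-step increments are assumed below the wrap limit), cumulatively
summed and scaled by `lambda / (4 pi n)`.  A space-time map averages
displacement over a 10-pixel band under the tracked top surface — the
wave energy is surface-weighted, and the band is configurable.

Group velocity uses time-of-flight regression: each lateral position's
arrival delay relative to a reference is the peak of the normalized
cross-correlation of mean-removed time profiles, refined by parabolic
interpolation (ties broken toward the smaller delay); speed is the slope
of the distance-vs-delay least-squares fit.  The reference is the first
position at least 3 lateral pixels from the excitation center, excluding
the near field.  A side estimate is invalid — not an exception — if
fewer than 5 usable positions exist, delays are degenerate, the slope is
non-positive, or R^2 < 0.8.  Left and right sides are averaged within an
orientation and the longitudinal/transverse means averaged per location.
The tracked feature is the full correlation waveform rather than a named
peak or leading edge, which is robust to amplitude decay; at 1 kHz with
a 3-cycle burst the acquisition window must hold the full burst
(500 time samples at 100 kHz suffice) or truncation biases the delay.

## Angiography

Flow contrast is `1 - mean ZNCC` over consecutive repeat pairs, with the
zero-normalized cross-correlation computed on linear intensity over a
5 x 5 (depth x lateral) kernel inside each B-scan; values are clipped to
[0, 1].  Constant (zero-variance) kernels count as perfectly correlated
when identical and uncorrelated otherwise.  Consecutive pairing (4 pairs
from 5 repeats) minimizes sensitivity to slow drift; bulk-motion
correction is not implemented because the phantoms are motion-free.

Vessels in the en-face maximum projection over the sub-surface depth
band are enhanced with the multiscale Hessian tubular filter
(`exp(-Rb^2/2 beta^2) (1 - exp(-S^2/2 c^2))`, bright ridges,
beta = 0.5, c = half the maximum Hessian norm, scales {1, 2, 4, 8} px),
normalized to [0, 1].  The mask (Otsu threshold on the lightly smoothed
response) is skeletonized; every third centerline pixel contributes one
flow profile sampled perpendicular to the local tangent, in physical
coordinates so anisotropic pitches are handled.  Tangents come from a
local PCA of skeleton pixels and points whose neighborhood is not
line-like (branch points, ragged spurs) are skipped.

Profiles are read from the 3-D flow volume at the point's strongest
depth (averaged over +/-3 axial pixels) rather than from the full-depth
projection: a projection takes, at every lateral offset, the *best*
kernel overlap across all depths and therefore widens every vessel by
roughly half a kernel.  The default profile model is a top-hat convolved
with the known kernel box blur (`sigma = kernel_px * pitch / sqrt(12)`),
and the fitted top-hat width is reported as the lumen width; a plain
Gaussian FWHM (2.355 sigma) is available as an option but biases small
vessels wide (kernel broadening) and large vessels narrow (plateau
mis-fit).  Fits with R^2 < 0.7 are discarded.  This automated
measurement replaces a manual caliper protocol; the deviation is written
into every run record.

## Statistics

Paired comparisons use the Wilcoxon signed-rank test with zeros dropped
(Wilcoxon's original treatment); between-group comparisons use the
Mann-Whitney U test.  Exact two-sided p-values (`2 min(lower, upper)`
tail sums, clipped at 1) come from the full null distributions, built by
dynamic programming and cached per sample size — signed-rank for
tie-free n <= 25, U for tie-free n1 + n2 <= 20; beyond that, normal
approximations with tie and continuity corrections.  At the crossover
the two branches agree within 0.02 for every attainable statistic.

Hodges-Lehmann estimates: two-sample, the median of all n1*n2 pairwise
differences (second sample minus first), with CI bounds at order
statistics whose ranks invert the U null distribution (exact pmf up to
n1 + n2 = 40, normal beyond); paired, the median of Walsh averages with
signed-rank inversion.  When the requested confidence is unattainable at
the given n, the widest achievable interval is returned with a warning
and the achieved confidence is reported.

Hedges' g uses the pooled SD and the small-sample correction
`1 - 3/(4 df - 1)`.  Sample size follows the two-sample normal
approximation `n = ceil(2 ((z_{1-a/2} + z_{pow})/g)^2)` — the default
because it reproduces the printed design arithmetic; a noncentral-t
solver (typically one unit larger) is available via `method="nct"`.
The minimum detectable difference is
`(z_{1-a/2} + z_{pow}) sd sqrt(2/n)`; with the pilot summaries
(pooled SD 0.255 m/s) and n = 15 it gives 0.26 m/s, about 16% of the
1.6 m/s group mean.

`run_study_analysis` evaluates a plan of comparison cells on a cohort
table; "pooled" sites average the two sites per animal before testing,
and the Bonferroni family is the whole plan (one output table), because
no finer family definition is available.  Cells that cannot be evaluated
are reported with a reason and still count toward the family size.

## Numerical and testing choices

Problem sizes in the test suite are scaled to desk proportions as the
package's own test design: structural phantoms of 128-A-line frames,
OCE records of 128 positions x 500 time samples, OCTA stacks of
64 x 256 x 128 voxels, 20-seed velocity sweeps across all six
excitation settings, 10^4-replicate type-I calibrations and
10^3-replicate CI coverage runs.  All randomness flows from explicit
seeds; identical spec and seed give byte-identical arrays and files
(run records list SHA-256 checksums of every output).

Known limitations: no bulk-motion or attenuation modeling; no
layer-resolved segmentation; no viscoelastic inversion or modulus
conversion; the cohort generator's non-anchored cells are invented
magnitudes; and the exact rank-test branches require tie-free data,
falling back to corrected normal approximations otherwise.
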