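# Methods

This note documents the models, numerical choices and limitations of
`fusmap`. It describes what the code computes; every empirical number
cited here is produced by the test suite or `scripts/acceptance.py`.

## Synthetic scene model

The generator's job is to produce data with exactly the statistical
structure the analysis assumes, with ground truth retained, so that
every downstream stage can be validated by parameter recovery rather
than by eyeballing maps.

**Geometry.** The imaging plane is a grid of `nz × nx` pixels (default
98 × 128) with 0.1 mm depth and 0.11 mm lateral pitch (≈10 × 14 mm
field). The cortex is a ribbon of constant thickness (default 2 mm)
around a mid-layer polyline; a straight ribbon is the default and a
Gaussian-dip "folded" path is available for sulcus-like geometry. Each
in-ribbon pixel gets a depth fraction (0 pia → 1 white matter) from its
signed normal distance to the densified path (10-µm steps, KD-tree
nearest point), an arc-length coordinate from the nearest path sample,
and a laminar label by indexing depth fraction with a configurable
fraction table (defaults: I 0–0.08, II/III 0.08–0.35, IV 0.35–0.60,
V 0.60–0.80, VI 0.80–1.0). These fractions are a reasonable laminar
split for quantitative work, not a claim about primate anatomy.

**Retinotopic preferences** vary linearly along arc length over the
stimulated ranges (eccentricity 1.5–15 DVA; polar angle 0–180°, one
hemifield, no wrap). **OD columns** are a square wave of the arc-length
coordinate: `od_column_width` (default 520 µm) is the width of one
eye's band, i.e. the half-period of the alternation — the full spatial
period is twice the width, which is why the spectral band for
350–700-µm columns runs from 1/(2·700) to 1/(2·350) µm⁻¹. Column
borders are sharp; the modulation is multiplicative on response
amplitude with a per-layer gain (default I 0.1, II/III 0.6, IV 1.0,
V 0.6, VI 0.1, mimicking a layer-IV-dominated pattern with weaker
expression above and below). Column widths at or below twice the depth
pixel pitch are rejected as unresolvable.

**Hemodynamics.** The impulse response is a gamma-density kernel
re-parameterized by peak delay (2.5 s) and FWHM (2 s), normalized to
unit peak; it is causal, unimodal and below 10⁻⁶ of peak by 10 s. The
gamma family was chosen because only the peak delay is an observed
constraint and a two-parameter unimodal causal kernel is the minimal
family consistent with 1-s averaging windows downstream. A trial's
response in a pixel is `amplitude × tuning × kernel(t − onset)`:
Gaussian tuning in the condition value (SD 1.5 DVA / 15°) for
retinotopic protocols, and `(1 + gain · od_phase · eye)/2` for
monocular protocols (matched eye drives the full amplitude, unmatched
`(1 − gain)/2`). The default peak amplitude is 16% ΔCBV — the scale of
a measured short-flash response — and a per-pixel Uniform(10, 40)%
amplitude option is available for heterogeneous scenes.

**Sessions.** Trials are condition-exact and randomly interleaved;
each costs 0.5 s fixation + stimulus + a 3-s intertrial gap (so onsets
are ≥ 4 s apart with 0.5-s flashes). An `extra_gap_s` knob adds slack:
the recovery analyses here use 8-s periods, and the trial-count
reliability analyses 15-s periods — at 8 s the preceding response's
tail overlaps the 5-s baseline window, which is realistic but makes
even noiseless trials differ slightly through their trial history;
15 s removes that confound where the analysis premise requires
identical noiseless trials.

**Noise** is additive i.i.d. Gaussian on Doppler intensity, expressed
in percent of baseline, so `response_amplitude / noise_sd` is the
single-trial pixel SNR (recovery tests run at 16/3 ≈ 5). The per-pixel
noise law of real recordings is uncharacterized; this is a stated
assumption, and spatially correlated or heavy-tailed noise is out of
scope.

**Ultrafast blocks.** For the clutter-filter stage the generator emits
complex 200-frame blocks at 500 Hz: a rank-≤3 tissue component (fixed
random smooth spatial patterns × slow complex sinusoids at 0.4/1.1/2.3
Hz, RMS `tissue_amp` times the blood RMS) plus per-voxel
Poisson-distributed moving scatterers whose frame-to-frame phase
advance is the axial Doppler shift 2·v·f₀/c (f₀ = 15 MHz, c = 1540
m/s, speeds uniform in a configurable 1–10 mm/s band, random sign).
Expected blood power per voxel is proportional to scatterer density,
which is what makes power Doppler a CBV proxy. `include_tissue=False`
with the same seed yields the blood-only twin used as the oracle for
filter-recovery tests. No beamforming, speckle or attenuation physics
is modelled — the blocks exist to give the SVD filter a faithful
low-rank-plus-diffuse structure, nothing more.

## Doppler formation

The Casorati matrix flattens each frame into a column; clutter removal
subtracts the `n_cut` leading singular components. Energy bookkeeping
(‖in‖² = ‖out‖² + Σ σᵢ²) holds to 1e−8 relative and is property-tested.
`n_cut` is a fixed configuration value (default 3, matching the
generator's tissue rank) because deterministic pipelines need a fixed
cut; an advisory elbow heuristic on the log singular-value curve is
provided but never applied implicitly. The physical reading of the
retained subspace (blood moving ~1–25 mm/s) is documentation, not an
explicit frequency band-pass. Frames are complex analytic signals and
power is the mean squared magnitude over the block.

## Preprocessing

Order is fixed: cubic-spline temporal upsampling (×10, exact at the
knots, ≥4 frames required) → 3-D smoothing → epoching → baseline
normalization. The smoothing kernel is a 3 × 3 × 3 box of Gaussian
weights with σ = 0.65 voxels, normalized to unit DC gain, applied with
nearest-value padding so the cortical surface rows do not ring. A
"box filter with an SD" is self-contradictory; a truncated normalized
Gaussian on a box support is the idiom such descriptions mirror, and
the kernel's exact shape is testable (impulse response, white-noise
variance reduction Σwᵢ²). Epochs span −5…+10 s around correct-trial
onsets; incomplete epochs are dropped with a warning; ΔCBV is percent
change from the 5-s pre-onset mean, so the baseline-window mean of
every trial is zero by construction. A regression test documents that
smoothing before versus after epoching changes interior epoch samples
by well under 1% CBV on noiseless data.

## Activation and reliability

Activation maps average the windowed response over trials. The
reliability analysis follows the resampling design exactly: trials of
one condition are split into notional 40-trial sessions; 20 random
trials form a reference map binarized at +10% ΔCBV; for each n in
1…20, 100 random n-trial combinations from the session's remaining
trials (disjoint from the reference, without replacement within a
combination) are averaged, binarized at the same threshold, and scored
as the fraction of pixels classified identically to the reference;
curves average combinations → session → grand mean. The Naka–Rushton
fit `p(n) = b + r·nᵉ/(nᵉ + n₅₀ᵉ)` uses bounded least squares from a
fixed grid of starts (n₅₀ ∈ {1, 2, 4, 8, 16}, e ∈ {0.5, 1, 2, 4}), so
it is deterministic; on noiseless curves it recovers generating
parameters to ~1e−14. Map SNR is defined as 10·log₁₀(mean active-ROI
response / SD of quiet-ROI values); the dB figures in the literature
come without a formula, so this definition is a package choice.

## Retinotopy

The per-pixel tuning fit is Gaussian + offset over the condition value
(not index), solved in two stages: a deterministic coarse grid over
(centre, width) with closed-form amplitude/offset (vectorized across
pixels), then bounded local refinement per pixel. Two constraints are
imposed deliberately: amplitude ≥ 0, because CBV responses are
positive bumps and unconstrained fits on noisy pixels produce inverted
Gaussians whose "centre" is meaningless; and width ≥ half the
condition spacing, because narrower tuning is unidentifiable from the
sampled curve and invites single-point spike fits. With both, centre
recovery at single-pixel SNR 5 is ≈95% within half a condition step
(Monte-Carlo, 1,000 pixels), and the residual failures are draws whose
global least-squares optimum genuinely sits elsewhere. R² is computed
against the flat-mean model; all-equal responses get R² = 0. The
validity gate R² > 0.02 is kept as stated in the source analysis, but
note it is permissive: a positivity-constrained Gaussian fitted to 9
noise responses clears it almost always, so on noise-dominated scenes
the gate mainly rejects degenerate pixels (this behaviour is pinned by
a test). Valid centres are clamped to the stimulated range. Map
post-filtering is 3 × 3 NaN-aware median → nearest-valid hole fill
inside the analysis mask → 1 × 3 lateral mean; filters never move
centres outside the stimulated range and never touch pixels outside
the mask. Polar angle lives on a linear 0–180° domain (one hemifield),
so no circular statistics are needed. Both the Gaussian SD and the
FWHM (2.355 σ) are exposed for bandwidth maps.

## Ocular dominance

Eye maps are z-scored over the analysis region (default: the crop
region itself) before subtraction; the OD map is antisymmetric in its
arguments by construction. The even/odd shuffle sends even-indexed
trials of both eyes to one side and odd-indexed to the other through
the identical standardize/subtract path, cancelling any consistent eye
preference. Layer segmentation takes top/bottom boundary polylines
(for synthetic ribbons these are generated by offsetting the mid-layer
path; for real data they would be traced), computes each pixel's
relative distance between the nearest points of the two paths, checks
that the paths do not cross, and indexes depth with the fraction
table.

Layer profiles collect OD values along the layer's arc coordinate
(origin at the first in-ROI column), bin them at a 100-µm pitch
(≈ pixel size; < 10 samples rejected), fill empty interior bins by
linear interpolation, and keep two versions: the raw uncentred profile
for the spectrum, and a centred smoothing-spline fit for extrema
detection. The spline penalty is chosen by generalized
cross-validation (`scipy.interpolate.make_smoothing_spline`), with a
fixed-`lam` override for reproducibility studies. Extrema require
prominence ≥ 0.75 and |value| > 0.25 OD-index units, evaluated on the
spline fit; the mean bandwidth pools half-distances between
consecutive maxima and consecutive minima (SEM reported as 0 with a
single half-distance). The spectrum is the one-sided FFT magnitude of
the raw profile (no zero padding), smoothed with a 3-sample moving
average and max-normalized; the spectral index is the in-band fraction
of total magnitude, DC included in the denominator — with DC retained,
a constant profile scores ≈0 and a white-noise profile scores the
band's share of the Nyquist range (≈0.143 at 100-µm pitch), both
pinned by tests. The index is scale-invariant and in [0, 1] always.

## Pipeline and problem sizes

`fusmap.pipeline.run` drives synth → preprocess → analysis from one
config; runs are deterministic per seed (sub-seeds are drawn once from
the master seed) and every report carries a hash of the scientific
parameters. The packaged test and acceptance runs use reduced planes
(e.g. 30 × 128 or 24 × 96 pixels, 6–8 trials per condition) rather
than the full 98 × 128 × 20-trial sessions: the analyses are per-pixel
and per-profile, so problem size affects runtime and Monte-Carlo
tightness, not the logic under test, and the reduced scenes keep the
whole suite fast while still spanning ~13 column periods laterally.
The full-size default remains available through `RunConfig()`.

## What passing tests do and do not show

The generator matches the analysis assumptions by construction —
Gaussian tuning, square-wave columns, gamma hemodynamics, i.i.d.
Gaussian noise, rank-3 clutter. Passing recovery tests therefore show
the pipeline is a correct and well-conditioned estimator under its own
model, including end-to-end through interpolation, smoothing and
z-scoring. They do not show robustness to what real awake-primate
recordings add: motion and tissue-interface artifacts, spatially
correlated and signal-dependent noise, vascular anatomy (radial
vessels that could smear columnar patterns), eye-position jitter, or
probe repositioning between sessions. Headline figures from real
recordings (classification percentages, measured bandwidths, dB SNRs)
are animal-data quantities; the package's corresponding numbers are
recoveries of its own ground truth and should be read as validation,
not replication.
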