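# Methods

## Scope and design

`pcnatrace` reimplements, as one coherent pipeline, the analysis used to
follow replication-associated proteins through the HeLa cell cycle by
two-colour live imaging (red: mCherry-PCNA; green: an EGFP-tagged protein of
interest). Because no image data are redistributable, the package closes the
loop on a synthetic generator instead: the generator *defines* the study
conditions (population phase-duration statistics, acquisition geometry, the
S-phase foci phenotype), and the analysis must recover them blind from the
rendered images. Segmentation and tracking are out of scope: nuclear ROI
masks and mitosis boundaries are inputs, as they were manual (or trivial)
steps in the original workflow.

## Cell-cycle timing model

Per-cell phase durations are independent draws from normal distributions
truncated below at 0.25× their mean (preventing non-physical durations;
only M, with mean 55 and SD 34 min, is noticeably affected — the truncation
raises its mean by ~7 min, under 1% of the cycle). Defaults (minutes):
G1 325 ± 73, S 420 ± 49, G2 158 ± 45, M 55 ± 34; mean cycle 958 min
(15 h 58 min). S is split early/mid/late at fixed fractions 2/7, 3.5/7,
1.5/7 (the 2 h / 3.5 h / 1.5 h split of a 7 h S). All cells start G1 at
t = 0: real cells are followed from their own division, so a common origin
loses no generality for a non-interacting population.

## Synthetic scenes

Nuclei are ellipses (aspect ratio 1–1.2, random orientation) whose area
grows linearly over interphase by a factor 1.6; during M the nuclear mask is
replaced by a rounded whole-cell mask 1.25× the nuclear radius and mean
levels drop by the archetype's mitotic-dilution factor (0.5 by default —
nuclear content dispersed over the larger cell volume). Acquisition
defaults: 0.23 µm pixels, 15-min frames, three Z-planes at 0.2 µm; the
out-of-focus planes are Gaussian-blurred (σ = 1 px) copies of the focal
plane (optical PSF modelling is deliberately out of scope). Intensities are
`intensity_scale` (2000 counts) × relative level, plus a constant background
(120) and additive Gaussian read noise (SD 50) per plane, stored as 16-bit
counts. Photon (Poisson) noise is omitted; it is not needed to exercise the
analysis. Nuclear radius at birth defaults to 30 px (≈ 7 µm, a realistic
HeLa nucleus at this pixel size). All randomness derives from the scene
seed, so a fixed seed yields a bit-identical scene.

### Replication foci

The paper-level phenotype — "many and small" foci in early S becoming
"fewer and larger", then dissolving — is rendered as isotropic Gaussian
spots with per-subphase parameters:

| subphase | count | radius (px) | peak/nucleoplasm ratio | placement |
| --- | --- | --- | --- | --- |
| early | 120–180 | 2–3 | 2.8 → 2.0 across the subphase | uniform |
| mid | 25–40 | 4 → 6 (ramp) | 3.0 → 4.0 | uniform |
| late | 8–15 | 6–9 | 4.0 → 1.0 | peripheral |

Counts and positions are frozen within a subphase and resampled at subphase
transitions. No quantitative foci statistics exist to fit; these constants
are *declared*, tuned once so that the mean Sobel-gradient trace of a
rendered nucleus reproduces the canonical shape: a steep jump at S entry, a
~2 h gently decreasing early-S plateau, a continuous ~3.5 h mid-S rise
peaking at the mid/late boundary (foci brighten and grow as they become
fewer), and a ~1.5 h late-S decline to the G1/G2 floor as the last foci
fade into the nucleoplasm (ratio → 1). The within-subphase intensity ramps
are what make the mid-S rise continuous and the late-S disappearance
gradual; a piecewise-constant model produces a staircase instead. The
mid-S starting ratio (3.0) was chosen so the trace is continuous at the
early/mid transition.

### Expression archetypes

Protein level curves are piecewise linear in control points
(phase, within-phase fraction, relative level), mapped onto each cell's own
boundaries, so a cell with a long G1 stretches its G1 segment. The five
bundled curves encode: RIF1 and MCM6 peaking 30 min into a mean G1
(fraction 30/325 of G1) then decaying to a plateau reached at S entry
(MCM6 with 2.5× amplitude, RIF1 nearly flat); ORC1 rising through G1,
holding ~2 h into S, falling to a nadir exactly at G2 start, then rising
through late G2 and M (chromatin-bound: exempt from mitotic dilution);
Claspin low through G1, rising from S onset to a plateau at mid-S held
until mitosis; PCNA rising through G1 into early S, more slowly to S end,
flat in G2. Chromatin-pattern decorations (peripheral rim for RIF1,
perinucleolar rings for MCM6) are rendered as mean-preserving multiplicative
texture, so the mean nuclear intensity still equals the archetype level.

## Trace extraction

Per frame: maximum-intensity projection over Z; mean ROI intensity minus
the background mean (complement of all cell masks eroded by 5 px — "the
area between cells"); and the mean Sobel gradient magnitude √(Gx²+Gy²)
over the same ROI. Choices worth stating:

* the Euclidean gradient norm, not |Gx|+|Gy| (anisotropic);
* Sobel is computed on the full projected frame with reflection padding and
  masked afterwards — filtering a masked image would manufacture gradients
  at the mask edge;
* no background subtraction for Sobel values (constant offsets have zero
  gradient), per-frame subtraction for intensities, which may leave small
  negative values (preserved, not clipped);
* slightly negative intensities and the Sobel noise pedestal (the gradient
  of read noise) are both constant-offset effects that the derivative-based
  caller ignores.

Tracking gaps (a cell's mask missing between its first and last appearance)
are recorded and logged, never silently skipped.

## Phase calling

The verbal criteria — S entry "the start of a steep increase" of the
Sobel trace, S exit "the end of a steep decrease" — are formalized as
follows (constants in `CallerConfig`; all detection happens strictly before
the annotated M start):

1. smooth the trace with a centred 3-frame moving average; differentiate;
2. baseline statistics from the first 25% of pre-M frames (well inside G1):
   median slope m and MAD; the effective scale is max(MAD, 0.5·|m|),
   flooring the MAD so the detector stays scale-free on noise-free traces
   dominated by secular drift (the nuclear border gradient drifts as the
   nucleus grows and PCNA expression rises);
3. candidate rises/falls are runs of ≥ 3 frames with smoothed derivative
   beyond m ± 3·scale **and** cumulative swing ≥ 25% of the trace's
   excursion over baseline — "steep" means the run moves a substantial part
   of the total signal, not merely that it dwells past a noise threshold;
4. S start is localised within the earliest rise, S end within the latest
   fall, at the midpoint of the first/last raw step exceeding a quarter of
   the run's mean step. The midpoint convention is unbiased with respect to
   where inside a 15-min frame interval the true transition fell;
   first/last-frame conventions carry a systematic half-frame-plus bias
   that distorts the short G2 by several percent.

A trace with no qualifying rise (or no subsequent fall) yields an explicit
no-S-detected outcome, distinct from invalid input — the correct answer for
a G1-arrested cell.

Within S: early S ends at the first ≥ 3-frame run of positive smoothed
derivative after the entry rise (the end of the plateau/decrease); mid S
ends at the first frame past the in-S maximum of the *unsmoothed* trace
(earliest tie). The unsmoothed maximum is used because the post-peak drop
is much steeper than the pre-peak rise, so smoothing displaces the peak
~2 frames early. If a subphase changepoint is missing or ordering is
violated, fixed fractions (2/7, 3.5/7, 1.5/7 of the called S) are applied
and the boundary is flagged `fallback`. Both per-cell calling and
average-profile segmentation are supported; the bundled acceptance analysis
segments the population-average profile.

Mitosis is an input, not a computation: rounded mitotic cells are obvious
to an annotator, and synthetic scenes know the truth.
`flag_mitosis_candidates` (a > 30% single-frame drop in green mean) is
advisory only. Raising the threshold multiple k can only shrink the
detected runs, so the called S phase never widens — a monotonicity the
tests assert.

## Normalization and averaging

Per cell, frame times are divided by the cycle length — operationally the
last observed frame time of the mitosis-to-mitosis track, which makes the
final unit time exactly 1. Each phase interval is then mapped affinely onto
the population-average phase proportions (computed from the cohort's called
timelines, or fixed externally for reproducibility), which places every
cell's boundaries on identical positions — conserved to machine precision,
as asserted in tests. Aligned traces are linearly interpolated onto a
common 64-point grid (≈ mean cycle / frame interval; the two-nearest-point
regression line *is* linear interpolation), clamped at the ends rather than
extrapolated (frames adjacent to mitosis are the noisiest). The axis is
rescaled by the mean cycle duration (cohort mean by default, 15.967 h when
configured to the published population mean) and averaged into mean ± sample
SD with n. Min-max scaling to [0, 1], used to compare shapes across
proteins, is applied to the averaged profile (a per-cell option exists).
During M the whole-cell mask stands in for the nucleus, so M-phase frames
remain in the average.

## Concentration calibration

A single mass-spectrometry concentration (any units; measured on an
asynchronous population) anchors a profile: the calibration factor is the
scalar divided by the time-weighted cycle mean of the profile, so the
output's cycle average equals the input scalar by construction.
Time-weighting assumes an asynchronous population samples the cycle
uniformly in time; an exponential-age option (density ∝ 2^(1−τ), young
cells over-represented in a growing culture) is provided. Negative
background-subtraction artifacts are clipped to zero and counted.
Fold-change statistics are quoted over interphase: mitotic frames reflect
redistribution of nuclear protein over the cell volume, not abundance. The
bundled MCM6 archetype, calibrated this way, fluctuates 2.5-fold.

## Problem sizes and determinism

The reference analyses run a 50-cell cohort at default imaging conditions
(~80 frames, ~740×850 px, three Z-planes, two channels) — about half a
minute to render and extract on one core — chosen as the cohort size at
which population means of the phase durations are determined to a few
percent. Unit tests use one-to-four-cell scenes. Every random choice flows
from a single integer seed (scene seed → per-cell, per-subphase, per-frame
substreams), so scenes, traces, calls and profiles are bit-reproducible.

## What passing tests do and do not show

The generator reproduces the *structure* that the analysis exploits —
S-restricted punctate texture with subphase-dependent grain, expression
curves tied to phase boundaries, mitotic dilution — but not optical
realism: no PSF, photobleaching, chromatic shift, cell motility or contact,
no segmentation errors, and Gaussian rather than photon-limited noise.
Recovery of the generating parameters therefore validates the measurement
chain and its conventions (projections, ROI statistics, changepoint logic,
alignment algebra), not robustness to imaging artifacts that real movies
add. The caller's constants (window 3, k = 3, min run 3, swing fraction
0.25) were fixed on noise-free single-cell geometry before any cohort run;
they are exposed in `CallerConfig` for real data, where drift and noise
structure will differ.

## Known limitations

* Foci constants are declared, not fitted to data; only the induced Sobel
  dynamics are constrained.
* The early-S "plateau or decrease" is realised as a mild decrease; a cell
  whose Sobel trace rises monotonically through S falls back to fixed
  subphase fractions (flagged as such).
* Alignment is landmark-affine per phase; no nonlinear (e.g. dynamic time
  warping) registration.
* Concentration anchoring ignores measurement differences between the
  tagged and endogenous protein pools.
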