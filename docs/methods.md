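# Methods

## Signal model and physiological rationale

The pipeline assumes two co-registered thermal signals sampled at
10 Hz in raw sensor counts: the nose tip, whose perfusion is strongly
modulated by sympathetic vasoconstriction, and the glabella, which
serves as a thermal reference.  Sympathetic activation cools the nose
tip relative to the glabella over tens of seconds; parasympathetic
recovery rewarms it.  Valence is inferred from the nose-tip signal
alone, arousal from the nose-minus-glabella difference, and the two
label streams are fused into six circumplex states.  No radiometric
conversion to °C is attempted: every statistic used (means of window
thirds, slopes, entropy over the window's own range, percentile and
band-power ratios, per-window z-scores) is either invariant to or
covariant with affine rescaling of counts, so the classifier operates
identically on any linear sensor scale.

## Imaging

Coordinates are 0-based with `x` = column, `y` = row and pixel centers
at integer positions; one convention had to be fixed for mask/oracle
agreement and this is the one used throughout.

**Calibration.**  A single planar homography per recording maps VIS
landmark coordinates into the IR frame.  A plane-to-plane model is
adequate because the face sits at an approximately fixed ~1 m distance
from the rigidly mounted camera pair.  The fit is the direct linear
transform in inhomogeneous form (bottom-right entry fixed at 1),
solved by linear least squares: exact for four correspondences in
general position, algebraic least squares for more.  Degenerate
(collinear, < 4 pairs) configurations raise a calibration error.

**ROIs.**  The published 68-point annotation does not come with an
official ROI composition, so the defaults are a documented choice:
glabella = triangle over the inner brow ends and the top of the nose
bridge (points 21, 22, 27); nose tip = quadrilateral around the nasal
tip, nostril corners and subnasale (30, 35, 33, 31).  Both are
configurable per call.  Masks are rasterized by the even-odd rule on
pixel centers with centers lying exactly on an edge counted inside;
the rasterizer is verified against an exhaustive point-in-polygon
oracle.  A mask is flagged *degraded* when a required vertex falls
more than a configurable margin (default 2 px) outside the frame;
degraded or empty masks produce missing samples rather than
interpolated data — downstream windows decide their own sufficiency.

## Valence classification

Windows are 20 s long with 2 s stride, starting at t = 0; each label
is emitted at the window end and describes the 20 s before it.  A
window is usable when at least 80 % of its samples are present
(interior gaps are linearly interpolated, edge gaps take the nearest
value); the 80 % threshold and interpolation rule are implementation
choices that keep isolated tracking dropouts from destroying whole
windows.  Unusable windows, and windows whose spectrum is degenerate,
emit NA — NA signals data insufficiency, never low classifier
confidence.

The eleven features: means of the first and last window thirds, the
difference between the first- and second-third means, Shannon entropy,
the 95th/5th percentile ratio, both coefficients of a first-order OLS
fit over the second and third thirds, the three coefficients of a
second-order OLS fit over the whole window, and the ratio of spectral
power in 0.04–0.15 Hz to 0.15–0.4 Hz.  Fixed estimator details:

* *Thirds* are contiguous equal splits with the remainder absorbed by
  the last third (200 samples split 66/66/68).
* *Entropy* is the Shannon entropy in nats of a 16-bin histogram over
  the window's own [min, max]; a constant window has zero entropy.
  This estimator is shift- and scale-invariant by construction.
* *Polynomial fits* are ordinary least squares against window-relative
  time in seconds.
* *Spectral ratio*: a 20 s window has 0.05 Hz native resolution, too
  coarse for the 0.04–0.15 Hz band, so the window is detrended (OLS
  line removed), zero-padded to 1024 points, and the one-sided
  periodogram integrated over each band by trapezoid.  Windows that
  are flat to machine precision after detrending are treated as having
  zero band power and emit NA.

The classifier is a soft-margin linear SVM (default C = 1, configurable)
on standardized features; training requires at least two examples per
class and is deterministic given its inputs.  Positive margins map to
parasympathetic.  The label mapping is fixed: sympathetic ↔ negative
valence, parasympathetic ↔ positive valence.  The originally deployed
model is not available, so models are trained on simulator-labeled
windows and persisted as JSON (weights, bias, scaling, feature names,
training metadata); a pre-trained model is checked into the test
fixtures for reproducible classification tests.

## Arousal classification

Windows are 8 s with 1 s stride over the difference signal.  Each
window is z-normalized (its own mean and standard deviation) before
the OLS slope against time is taken, which makes the slope scale-free
and exactly invariant to additive offsets of either input; a
zero-variance window has slope 0 by convention.  More negative slope
means stronger nose-tip cooling and higher arousal — the direction
follows the vasoconstriction physiology; the boundary assignment uses
≤ at both cut points so ties go to the stronger response.

The published system derived its cut points from data that are not
available, so calibration is explicitly parameterized: all 8 s / 1 s
slopes of a baseline recording (≥ 60 s) are enumerated and t_high /
t_low taken as the 10th / 50th percentiles of that distribution
(configurable, persisted with the outputs).  No attempt is made to
reproduce the original numeric thresholds.

## Fusion and occurrence summaries

Each valence emission (2 s cadence) is paired with the most recent
arousal emission at or before its time — "simultaneous" had to be
resolved across the 1 s and 2 s grids and most-recent-at-or-before is
the causal choice.  The 3 × 2 table is fixed: (high, positive) →
excited, (high, negative) → tense, (medium, positive) → focused,
(medium, negative) → cautious, (low, positive) → calm, (low, negative)
→ bored; NA valence or absent arousal yields NA.  Occurrence tables
report the share of each state among non-NA emissions to two decimals
without renormalization, so aggregates over the printed cells preserve
any rounding artifact instead of forcing the sum to 100.

## Event-locked analysis

The 10 s after each question onset is divided into five 2 s segments.
Membership uses half-open intervals (t0 + (k−1)·2, t0 + k·2], so each
2 s emission falls in exactly one segment and an emission exactly at
the onset is excluded; when consecutive question windows overlap, the
most recent question claims the shared emissions (logged).  NA
emissions are discarded throughout.  Normalization is the fraction of
non-NA emissions per segment; per participant, fractions are averaged
without weighting over that participant's questions, and segments with
no emissions are skipped rather than zero-filled.  The segment-wise
test is a paired two-sided Student's *t* between the sympathetic and
parasympathetic fractions across participants ("paired" because both
fractions come from the same participant; the module also reports the
raw mean difference).  Zero-variance paired differences leave the
statistic undefined and are flagged; all-zero differences report
t = 0.  Because the two fractions sum to one per cell, the test is
equivalent to testing the mean difference against zero.

## Synthetic data

The generator is a stand-in for unavailable patient recordings, not a
physical thermal renderer.  Glabella = baseline (7000 counts) + slow
sinusoidal drift (default amplitude 2 counts, period 120 s) + Gaussian
sensor noise; nose = the glabella's deterministic part + a cumulative
ANS offset + independent noise.  The offset falls at the sympathetic
cooling rate during sympathetic episodes, rises at the recovery rate
during parasympathetic episodes, and holds otherwise — a
piecewise-linear caricature of vasomotor dynamics.  Defaults define
the reference signal-to-noise condition: 0.25 counts/s episode rate
(5 counts across a 20 s analysis window) against 0.5 counts of noise,
chosen so the valence classes are learnable but not trivially
separable.  The default episode schedule alternates 30 s sympathetic
and parasympathetic episodes separated by 10 s of neutral, matching
the tens-of-seconds time scale of nasal thermal responses.  Every
stochastic draw is governed by a mandatory seed and reproducible
bit-for-bit.

Question onsets trigger a configurable post-question episode, by
default a parasympathetic rebound starting 4 s after the question and
lasting 2 s — the direction of the empirical post-question response
pattern.

Ground truth is deterministic given the configuration: the per-sample
latent state; per 20 s window, the majority state (ties break
sympathetic > parasympathetic > neutral); per 8 s window, an arousal
label obtained by thresholding the *expected* z-normalized slope under
the generative model — the raw noiseless slope divided by the total
window standard deviation including the 2σ² noise variance of the
difference signal — at fixed symmetric cut points ±0.2 1/s (a clean
monotone 8 s ramp scores ≈ ±0.43, a flat window 0).  This expectation
is the large-sample limit of the noisy estimator; the plain z-slope of
the noiseless signal is not, because z-normalizing a nearly flat
window amplifies arbitrarily small transients.  Finally, the simulator
exposes the idealized zero-lag valence stream: the latent state
sampled just before each 2 s emission instant, with neutral mapped to
NA.

The frame simulator renders the two series into flat rectangular
patches over a noisy background, with the ROI polygons strictly inside
their patches, so ROI extraction recovers the series exactly (to
double precision) at zero sensor noise regardless of the polygon
shape.  Landmarks are emitted in VIS space consistent with a known
half-scale-plus-shift VIS→IR homography.  Frames are float64 in
memory (one frame per sample), so frame-level work uses short
durations; on disk, stacks are quantized to 16-bit TIFF.

**What the simulator does not emulate** — and hence what passing tests
do not show about real data: facial appearance and landmark-tracking
failure modes, motion and perspective change, breathing artifacts,
radiometric drift and dead pixels, inter-individual variability of
vasomotor gain, and overlapping or graded ANS states.  Recovery
figures (valence hold-out accuracy ≥ 0.9, arousal window agreement
≥ 0.85 at the reference noise condition) validate the implementation
against its own generative assumptions, not clinical performance.

## Problem sizes and evaluation choices

Test and acceptance runs use 300 s recordings (141 valence / 293
arousal windows), 400 training windows per class with disjoint
training and evaluation seeds, 8 simulated participants with 9
questions each for the event-locked analysis, and 100 seeded cases per
numerical primitive for the oracle-equivalence checks.  Homography
oracle comparisons use calibration-target-style point sets (four
anchor corners plus extras on a normalized square): with
nearly-collinear random configurations, the comparison of two exact
least-squares solvers is dominated by conditioning rather than
implementation agreement.

Valence-agreement evaluation is restricted to windows whose majority
ground-truth state is sympathetic or parasympathetic, since the
classifier has no neutral class.  The event-locked rank property (the
4–6 s segment carrying the maximal parasympathetic − sympathetic
difference) is evaluated on the simulator's idealized zero-lag
emission stream.

## Known limitations

* Any causal 20 s-window valence classifier detects a short autonomic
  response with roughly half-window latency: a 2 s rebound 4–6 s after
  a question shifts window features most strongly for emissions
  ~10–14 s after the question, and a 2 s episode can never flip a 20 s
  majority.  Event-locked analyses of classifier output therefore
  smear short responses into later segments; segment-resolved claims
  at 2 s granularity require the idealized (or an external, low-latency)
  valence stream.
* The arousal cut points are percentile conventions, not reproductions
  of the originally deployed thresholds, and the trained valence model
  reflects the simulator's feature distribution only.
* The homography model ignores lens distortion and depth parallax;
  both are below ROI scale at ~1 m subject distance but matter for
  close-range setups.
* `aggregate_occurrence` sums rounded table cells by design; summing
  all six states can differ from 100.00 by a rounding artifact.
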