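# Methods

This note documents the models implemented in `glucotrack`, the
parameter defaults and why they were chosen, what the synthetic-data
generator does and does not emulate, and the numerical decisions made
where the design was genuinely open.

## The scientific question

A sensor can relay an input's current value (proportional tracking) or
its rate of change (derivative tracking); the two modes produce
distinguishable temporal signatures.  Around a glucose infusion,
proportional coupling predicts a neural response that is a (possibly
delayed, possibly inverted) copy of the glucose waveform and a monotonic
activity-vs-glucose relation; derivative coupling predicts a response
confined to the rising/falling phases that *anticipates* the glucose
peak, and an open activity-vs-glucose loop (hysteresis).  The package's
analyses — lagged cross-correlation, epoch contrasts, hysteresis areas,
an encoding model with derivative predictors, and single-cell template
classification — all probe exactly this distinction.

## Synthetic sessions

### Glucose transient

An infusion-evoked transient is modeled as bi-exponential
absorption/clearance,

    G(t) = B + A·k·(e^{−(t−t₀)/τ_c} − e^{−(t−t₀)/τ_a}),  t ≥ t₀,

with `k` normalizing the bracket so the noiseless peak sits exactly `A`
above baseline `B`, plus white telemetry noise (sd 0.15 mM) throughout.
This is the simplest shape with separate rising and falling phases —
which is all the derivative-vs-proportional analyses need.

Defaults: `B = 7.3 mM`, `A = 7.0 mM`, `τ_a = 9 min` (14 min for the
intragastric route, which differs only in slower absorption),
`τ_c = 27 min`.  These were chosen once so the noiseless transient sits
inside *all three* physiological ranges typical of such experiments
simultaneously — baseline 3.5–11.1 mM, peak 11.1–34.9 mM, maximum rate
of change 0.12–1.45 mM/min — and peaks ≈ 15 min post-infusion so the
canonical epoch windows straddle the peak.  A bi-exponential's maximum
slope occurs at onset, so reproducing the *mean* observed peak
(≈ 24 mM) while staying under the rate ceiling is impossible with this
shape; the ranges were prioritised over the means.  The generator
checks the realized noiseless peak and maximum rate post hoc and warns
when either leaves its range.

### Locomotion, metabolics, temperature

Running is a bout point process: Poisson start times (default
0.02 s⁻¹), exponential-tailed durations ≥ 1 s (mean 4 s), speeds drawn
strictly above the 18 cm/s detection threshold, zero between bouts.

Gas exchange couples with lagged exponential kernels: VO₂ (baseline
0.002 l/min, mouse-scale) rises with running (30-s kernel); the
respiratory exchange ratio (baseline 0.85) drifts upward after the
transient (5-min kernel, +0.10 at peak) so VCO₂ = RER·VO₂ rises;
body temperature (37 °C) rises slowly post-infusion (10-min kernel,
+0.6 °C).  Each channel additionally carries an *independent* slow
fluctuation process (intrinsic metabolic variability; e.g. 15% of
baseline for the gas channels, 0.3 °C for temperature) plus fast sensor
noise.  The independent components matter: without them every channel
is a deterministic function of running and glucose and the encoding
model's predictors become nearly collinear, which the multivariate
design presumes away (pairwise predictor correlations should stay well
below 0.8).  These couplings are placeholders calibrated only for the
sign and rough size of the effects, not for quantitative gas-exchange
physiology.

### Single cells

Each cell draws a glucose class (G, dG, iG, idG or no-response) and a
running class (positive/negative/none).  Its 5-Hz trace is

    slow_gain·class_waveform + running_gain·(indicator ⊗ speed)
      + optional bleach trend + white noise,

where the class waveform is the same transformation the classifier's
templates use (1.5-min moving-mean smoothed glucose, derivative
re-smoothed after differentiation, negated for inverted classes),
normalized to unit SD over the session, so `slow_gain / noise_sd` is the
slow-signal SNR; the locomotion regressor is speed convolved with a
single-exponential calcium-indicator kernel (τ = 1.5 s) and z-scored.
Defaults: slow gain 5, running gain 1, noise sd 1, lognormal gain jitter
(σ = 0.25).  When the session has no infusion the cells' glucose input
does not fluctuate and slow gains are zero.

Class prevalences default to the canonical mixture
G 24.5%, dG 10.8%, iG 32.3%, idG 30.4%, no-response 2% (i.e. roughly
two thirds of cells glucose-inhibited).  Per-class response amplitudes
default to G 1.25, dG 0.4, iG 1.0, idG 1.0: derivative-activated cells
respond weakly and the two proportional classes nearly cancel in the
sum, which is what makes the *population* trace resemble the
derivative-inhibited template — the mechanism the single-cell survey
itself suggests for the population-level signature.

Population activity is the cell-mean resampled to 1 Hz and z-scored to
the 20-min pre-infusion window.  A raw-fluorescence channel for testing
the detrender is produced separately as
`F = F₀ · bleach(t) · (1 + 0.05 · activity)` with a triple-exponential
bleach (default ≈ 30% decay over a 90-min session) — exactly the
structure the detrender assumes.

### What the generator does not emulate

No pharmacokinetic realism beyond the printed ranges; no
counter-regulatory undershoot; no motion artifacts or hemodynamic
contamination (hence no control-channel regression); no spike-level
dynamics (cells are Gaussian around their mean waveform); no anatomical
structure.  Passing recovery tests therefore demonstrates the
*analyses* are correct and self-consistent, not that real recordings
will behave this cleanly — in particular real no-response cells are
noisier and real metabolic couplings are richer.

## Preprocessing

"Fit through the trace minima" is implemented as the lower convex hull
of the full raw trace (Andrew monotone chain on (t, y); collinear
vertices retained; first and last samples always included), which is
deterministic and parameter-free.  The baseline is a least-squares
triple exponential **plus constant offset** (7 parameters) fitted
through the hull vertices with bound-constrained least squares from a
deterministic grid of 27 starts (τ guesses at 0.01/0.1/1 × trace
duration per component); best residual wins.  Fewer than 8 support
points fall back to two components, fewer than 6 to one, fewer than 4
is an error; the component count is recorded in the model.  Moving
means are centered with shrinking (truncated) edge windows — no data is
fabricated at session boundaries.

The hull-floor assumption means detrending is accurate when the trace
rides *above* its bleaching envelope (upward transients, or noise-dips
marking the floor).  A population that is deeply and persistently
inhibited pushes real signal onto the hull and the baseline absorbs
part of it; the recovery test uses a glucose-activated population for
exactly this reason, and the same caveat applies to real inhibited
recordings.

## Temporal analysis

Derivatives are central differences (one-sided at edges) scaled to
per-minute units.  Cross-correlation is per-lag Pearson r on the
overlapping segments, positive lag meaning the second series is
delayed; the peak is the extremum of |r|.  Transient boundaries use a
baseline mean + 3 sd threshold sustained for 60 s (the persistence
makes the rule robust to telemetry noise); the offset falls back to the
last sample when glucose never returns.  Hysteresis loops take 50
points equally spaced *in time* across the transient (equal spacing in
glucose is ill-defined on a non-monotonic transient); the signed area
is the shoelace sum over the ordered polygon, so a counterclockwise
traversal — activity below during the rise, above during the fall, the
signature of inverted-derivative coupling — is positive.  Epoch windows
are half-open `[start, end)` minutes so the canonical set
(−11..−2, 2..11, 11..20) tiles without overlap.  Bout detection merges
super-threshold runs separated by ≤ 2 s first and applies the ≥ 1 s
duration rule after merging, making the two rules compose
deterministically.

## Encoding model

All channels are block-averaged to 1 min, Savitzky–Golay filtered
(first order, five samples), differentiated *after* filtering, and
z-scored (response included).  The model is ordinary least squares with
intercept — an identity-link Gaussian GLM.  Each bootstrap iteration
tiles the rows into contiguous quarter-duration chunks at a uniformly
random phase (4–5 chunks), randomly accumulates chunks into the
training set until it holds ≥ 70% of rows, and validates on the rest —
chunking preserves the temporal autocorrelation inside folds, which is
the point of chunked resampling on time series.  ΔR² per predictor is
clipped at zero per iteration, aggregated by median (means also
reported), and normalized to percent of the summed medians, making
rankings scale-free.  Contributions are reported as all-zero with a
flag when every clipped ΔR² is zero *or* when the full model's median
validation R² is ≤ 0 — under the null, clipping before the median
leaves small positive ΔR² medians, so the model-level check is what
actually catches uninformative fits.  The leave-one-session-out mode
holds out whole sessions as validation folds and is used to confirm
bootstrap rankings on multi-session data.  Z-scoring happens per column
before chunk selection, and derivatives before z-scoring; both choices
are recorded in the fit provenance.

## Single-cell classification

Templates are built from a *held-out* session (in the pipeline: a
separate seed stream with the same infusion protocol), smoothed with a
1.5-min moving mean before transformation, derivative templates
re-smoothed after differentiation, cropped to the first 20 min
post-infusion, and centered/unit-scaled (so iG = −G and idG = −dG hold
exactly and prevalence-weighted reconstructions are on a common scale).
Cell traces are aligned to the template grid by linear interpolation.
Correlation p-values use the two-sided t-approximation on the aligned
samples; autocorrelation inflates significance (as it would on the real
5-Hz traces), which is why the no-response rule needs the conservative
α = 0.001/4 threshold.  Exact-r ties break in the fixed order
G → dG → iG → idG.  Repeated same-condition sessions are averaged per
cell before classification.

The running classification (whole-session Spearman, positive if
p < 0.05 and ρ > 0.01, negative if p < 0.05 and ρ < −0.01) is
deliberately liberal: at n ≈ 27,000 samples almost any systematic
correlation is significant, and autocorrelated slow components produce
spurious |ρ| > 0.01 in most truly uncoupled synthetic cells.  Coupled
cells recover their sign essentially perfectly; the 'none' class — and
hence the multiplexed fraction — is upward-biased in synthetic runs
with strong slow signals.  This is a property of the thresholds, not of
the implementation.

## ROI matching

Masks are dilated by a Euclidean disk of radius 3 (a 29-pixel disk for
a single pixel), clipped at the 256×256 frame.  Overlap is
|A∩B| / min(|A|,|B|) on the dilated masks — lenient to partially imaged
cells across planes, which is the cross-plane use case; union
(Jaccard) normalization is available by flag.  Trace agreement is the
maximum Pearson r over integer-sample lags strictly inside ±2 s at
5.1 Hz.  "Neighboring planes" means plane-index distance ≤ 1.  Joins
require all five criteria (adjacency, overlap > 5%, r > 0.90,
|lag| < 2 s, ≥ 2 supporting sessions); groups are connected components
over joined pairs and merged traces are member means.  Masks travel as
integer label arrays or run-length CSV tables.

## Determinism, sizes, limitations

Every stochastic stage consumes an `numpy` `SeedSequence`-derived
generator, so all outputs are pure functions of (config, seed); the
pipeline report hashes identically across reruns.  Default problem
sizes — 90-min sessions at 1 Hz, 5-Hz cell traces, 100–400 cells,
200 bootstrap iterations in tests and the acceptance script (2,000 is
the production default) — were chosen so a full validation run
completes in minutes on one core while keeping recovery statistics
well-powered.  Known limitations: the detrender's floor assumption
under deep sustained inhibition (above); the liberal running thresholds
(above); correlation p-values that ignore autocorrelation (a
block-permutation alternative would be the conservative upgrade); and
the generator's placeholder metabolic couplings.
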