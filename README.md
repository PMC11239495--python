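# glucotrack

Analysis tools for experiments that ask **what temporal feature of blood
glucose a neural population tracks** — the concentration itself
(proportional tracking) or its rate of change (derivative tracking).
The package targets multichannel recordings in behaving mice in which
hypothalamic neuron activity (fiber photometry or volumetric two-photon
imaging) is monitored together with blood-glucose telemetry, wheel
running, respiratory gas exchange (VO₂/VCO₂) and body temperature around
a glucose infusion.  It is aimed at systems-neuroscience and physiology
labs analysing such recordings, and it ships a first-class synthetic
session generator with ground-truth labels so every analysis can be
validated by parameter recovery.

## What it computes

**Photometry preprocessing.** Raw fluorescence is detrended by fitting a
least-squares triple exponential `f(t) = Σᵢ aᵢ e^(−t/τᵢ) + c` through the
lower convex hull of the trace (the bleaching floor), forming
`(F − f)/f`, then z-scoring against the 20-min pre-infusion window.

**Temporal analysis.** First derivatives (mM · min⁻¹), lagged Pearson
cross-correlation, OLS linear fits with slope tests, glucose-transient
boundary detection, 50-point hysteresis loops with signed (shoelace)
area, canonical epoch means (baseline −11..−2 min, high-derivative
2..11 min, high-absolute 11..20 min relative to infusion), the Weir
energy-expenditure formula `EE = 3.94·VO₂ + 1.1·VCO₂` (kcal · min⁻¹),
RER = VCO₂/VO₂, and locomotion bout detection (super-threshold runs
≥ 1 s, merged when separated by ≤ 2 s).

**Encoding model.** Population activity on a 1-min grid is regressed on
ten z-scored predictors (running, glucose, temperature, VO₂, VCO₂ and
their derivatives).  Per bootstrap iteration the session is tiled into
quarter-duration contiguous chunks at a random phase, chunks are assigned
70/30 to train/validation, and each predictor's contribution is the
validation-R² drop when it is removed (ΔR², clipped at 0).  Median ΔR²
values are normalized to percent contributions; a leave-one-session-out
mode cross-checks the bootstrap.

**Single-cell classification.** Four templates are built from a
(held-out) glucose transient — smoothed glucose G, its smoothed
derivative dG, and inversions iG, idG.  Each cell, aligned to the first
20 min post-infusion, joins the class with maximal Pearson r unless no
template correlation beats the Bonferroni threshold α = 0.001/4
(no-response class).  Cells are separately classed by whole-session
Spearman correlation with running (positive / negative / none), the two
axes are cross-tabulated to quantify glucose × locomotion multiplexing,
and the population response is reconstructed as
Σ prevalence × amplitude × template.

**ROI identity matching.** Cell masks from different sessions/planes are
joined when the same cell is evident: adjacent planes, > 5% overlap of
3-pixel-dilated masks, trace correlation > 0.90 at |lag| < 2 s, and at
least two supporting sessions; joined pairs merge by connected
components.

## Worked example

```bash
glucotrack simulate --seed 7 --n-cells 150 --out-dir demo
glucotrack xcorr demo/session.csv --derivative --out demo/xcorr.csv
glucotrack encode demo/session.csv --iterations 200 --seed 0 --out demo/encode.json
glucotrack classify demo/cells.csv demo/session.csv --out demo/classes.csv
glucotrack hysteresis demo/session.csv --out demo/loop.csv
glucotrack epochs demo/session.csv --out demo/epochs.json
```

prints

```
peak r=-0.828 at lag -5 s
top predictor: d_glucose (99.1%)
{"G": 0.253, "dG": 0.127, "iG": 0.313, "idG": 0.28, "N/A": 0.027}
signed area +40.9546 over (1526.0, 5399.0)
{"baseline": 0.160, "deriv": -4.436, "abs": -0.405}
```

Reading the output: population activity is strongly *anti*-correlated
with the glucose derivative at essentially zero lag (r = −0.83) — the
population is inhibited while glucose rises, not while it is high.  The
encoding model attributes almost all explainable slow variance to the
glucose derivative.  Classified single cells split into
proportional/derivative, activated/inhibited classes near the generating
prevalences, with a small no-response remainder.  The activity-vs-glucose
loop over the detected transient (onset 1526 s) has a large positive
signed area — the hysteresis signature of derivative coupling — and the
epoch means show inhibition confined to the high-derivative window
(−4.4 z) with near-baseline activity in the high-absolute-glucose window.

The same pipeline runs end-to-end in one call (`glucotrack report
--seed 7 --out-dir out/`), writing `report.json` with every stage's
summary; Python users can call `glucotrack.run_pipeline(PipelineConfig(...))`
directly.

## Layout

```
src/glucotrack/
  simulate.py     synthetic sessions + ground truth (glucose kinetics,
                  locomotion bouts, metabolics, cell mixtures)
  preprocess.py   hull-based detrending, z-scoring, conditioning
  temporal.py     derivatives, cross-correlation, transients, hysteresis,
                  epochs, Weir/RER, bouts
  encoding.py     chunked-bootstrap leave-one-predictor-out ΔR² model
  classify.py     glucose templates, cell classes, running correlation,
                  multiplexing, population reconstruction
  roi.py          ROI dilation/overlap/lag matching, component merging
  io.py           session/cell CSV + JSON sidecar formats
  pipeline.py     end-to-end orchestration and reports
  cli.py          command-line interface
```

See `docs/methods.md` for the model assumptions, parameter defaults and
known limitations.
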