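# Methods

## Event inference model

The pipeline assumes a fixed camera, a single pig per pen, and one or two
wall-mounted faucets whose image positions do not move within a session.
Under those assumptions drinking can be inferred geometrically: the pig's
head centroid must sit essentially on top of a faucet centroid for a
sustained period.

**Proximity score.** For a head centroid and a fixed faucet centroid at
Euclidean pixel distance `d`, the score is `P = 1 - d / d_diag`, with
`d_diag` the frame diagonal. Normalizing by the diagonal makes the 0.98
threshold resolution-independent: at 1280×720 (`d_diag ≈ 1469 px`) it
corresponds to ~29 px of separation, at 640×480 to 16 px. The distance
metric is Euclidean in pixel space; with a top-down camera at fixed height
this is proportional to distance on the pen floor.

**Threshold comparison is inclusive** (`P ≥ 0.98`). The boundary case must
be deterministic, and inclusiveness keeps the published constant itself
attainable (a head exactly 16 px from the faucet in a 640×480 frame flags).

**Faucet localization.** All `Water-Faucet` detections in the first 30
frames are greedily clustered by centroid distance; a detection joins the
first cluster within 5 % of the frame diagonal, else opens a new one. Each
cluster is represented by its highest-confidence member, and the top one or
two clusters by confidence become the fixed faucets (ids in descending
confidence order). The 5 % radius is a design choice: repeated detections of
one faucet jitter by a few pixels, while distinct faucets in a pen are far
apart, so any radius between those scales works; 5 % sits comfortably
between them. Zero faucet detections in the window raise an error —
monitoring cannot start without a reference.

**Flagging and segmentation.** Per frame the score is maximized over all
head–faucet pairs (detectors emit duplicate heads; no identity tracking is
attempted in a single-pig pen). Maximal runs of flagged frames become
events; `max_gap_frames` (default 0, a *continuous* run) optionally bridges
short dropouts, which matters at heavily downsampled review cadences where a
single missed frame spans ~0.7 s. Events shorter than `min_duration_s`
(default 5 s) are discarded: brief faucet contact is habitual
sniffing/curiosity, not intake. The minimum is applied at segmentation time,
so analyses at other thresholds only need to re-segment. Each event is
attributed to the faucet with the highest mean `P` over the run, ties to the
lower faucet id.

Frame timing is `t = frame_index / fps`, and all frame intervals are
half-open `[start, end)`, so durations are exact multiples of the frame
period and adjacent events cannot share a frame.

## Validation

Frame-level confusion (accuracy, precision, recall, F1) compares the
flagged-frame track against a human 0/1 annotation of the same frames. When
a downsampled review cadence is needed, every `stride`-th frame is kept
(stride 18 turns 25 FPS into 25/18 ≈ 1.389 FPS); stride decimation was
chosen as the simplest deterministic scheme. Precision with zero predicted
positives is reported as 0 with a warning rather than NaN so batch
validation never crashes.

Temporal concordance unions each side's event intervals first, then reports
interval intersection-over-union plus the model-only and truth-only
fractions of the union. The implementation is an exact sweep over sorted
interval endpoints; tests pin it against per-millisecond rasterization.

## Behavioral characterization

Events are binned by the clock hour of their start; an event spanning an
hour boundary counts wholly in its start hour. Hourly *drinking power* is
`count × mean duration` (seconds) and is always recomputed from those two
factors rather than trusted from any pre-tabulated product. The stratified
contrast compares the mean hourly power share of the feeding-related hours
{8, 9, 13, 14, 15} (dry feedings around 07:00 and 13:00) with the remaining
lights-on hours {6, 7, 10–12, 16–18}; the all-hours reference mean is
`100 / n_observed_hours` percent, so relative power of 100 % means an
average hour.

Dispersion statistics use the **population denominator** (`ddof = 0`)
throughout: the six monitored days of a pig are treated as the complete
record of the period being described, not a sample from a longer process.

Group comparison uses tie-corrected Kruskal–Wallis (preferred, since daily
counts are small-sample and one animal's counts are clearly non-normal by
Shapiro–Wilk), with classical one-way ANOVA reported for reference. The
statistics are computed by scipy; independent midrank and two-group `F = t²`
oracles in the test suite guard the contract.

**Illness indicator.** A day is flagged when its event count deviates from
the baseline median `m_b` of a designated healthy window (≥ 3 days, same
animal — each pig is its own control) by more than `k·s_b` (absolute mode,
`s_b` the population std of the baseline window, default `k = 2`) or more
than `r·m_b` (relative mode, default `r = 0.4`). Both modes are exposed
because the two published formulations of the rule are mutually
inconsistent; the defaults follow the prose (two baseline standard
deviations, or a 40 % swing). On a stationary Poisson-like baseline the
absolute rule at `k = 2` false-flags well under 10 % of days.

## Reference dataset

`penwatch.datasets` ships the printed measurements of an 18 pig-day
monitoring study (three Göttingen minipigs, six days each, 06:30–18:30
lights-on): aggregate hourly event counts and mean durations, and per-day
event counts, total drinking times and mean durations per animal. Two known
print inconsistencies are handled deliberately: one hourly power cell is a
digit transposition of its own factors (count × mean reproduces the printed
column total, the printed cell does not), so power is recomputed from the
factors; and the published overall median/std row of the daily counts is not
reproducible from the per-day counts and is not asserted anywhere.

## Synthetic pen simulator

The simulator emulates the monitoring setup, not its photometry: it
produces detection streams directly, skipping rendering and detector
inference. What it models:

* **Schedule.** Visit starts are an inhomogeneous Poisson process over
  clock hours. The default intensity is proportional to the observed
  aggregate hourly counts (bimodal: morning 08–10 and a dominant afternoon
  14–16 peak), scaled to 34 visits per 12 h day (612 events / 18 pig-days).
  Durations are lognormal with median 30 s and sigma 0.8 (mean ≈ 41 s,
  matching the observed 41.44 s overall mean), floored at 6 s so every
  scheduled visit can clear the 5 s event filter. Overlapping candidates
  are thinned in start order with a 5 s minimum gap. A flag confines visits
  to single clock hours when exact hourly-binning tests need it.
* **Motion.** Between visits the head centroid follows a bounded random
  walk (step 2 % of the frame diagonal per frame — arbitrary but plausible,
  and configurable) kept more than 3 % of the diagonal away from every
  faucet (`P < 0.97`); during visits it is pinned within 1 % of the assigned
  faucet centroid (`P ≥ 0.99`). Transitions are instantaneous, which is why
  zero-noise recovery is exact to the frame.
* **Detector noise.** Independent per-frame head misses, Gaussian corner
  jitter, spurious low-confidence `Feces`/`Pig-Head` boxes at a Poisson
  rate (the detector's observed background confusions), and Beta-distributed
  confidences (high-concentration for real objects, low for spurious ones)
  so confidence-ranked faucet localization is genuinely exercised. The
  all-zero noise model is the default and the reference for recovery tests.

What it does **not** model: occlusion structure (misses are i.i.d., real
occlusions are bursty), posture dynamics (`Pig-Standing` is a placeholder
box), lighting, multiple animals, or correlated faucet drift. Passing
zero-noise tests therefore demonstrates the correctness of the inference
and analytics arithmetic, not detector robustness on real video; the
published frame-accuracy figures from real footage are not reproducible
here and are not claimed.

## Problem sizes and numerics

Tests run sessions of 0.5–2 h at 2–5 FPS; the acceptance script simulates a
full 12 h day at 5 FPS (216,000 frames, a few seconds of compute). The
proximity threshold comparison, interval arithmetic and rank statistics are
exact; the only tolerances in the suite are print-precision tolerances on
published table values and 1e-9/1e-10 agreement bounds against the
rasterization and midrank oracles. Degenerate inputs are defined, not
special-cased: empty streams yield empty event lists, an empty day yields a
zero-count summary, constant samples yield `H = 0` and an error for the
normality test (undefined on zero variance), and ANOVA refuses zero
within-group variance with unequal means.
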