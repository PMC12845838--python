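# penwatch

Camera-based monitoring of drinking behavior in singly-housed pigs, built
for research facilities that film each pen from a fixed, top-down camera and
run an object detector over the footage. `penwatch` takes the detector's
per-frame bounding boxes — it is detector-agnostic — and turns them into
*drinking events*, validates those events against human annotations, and
computes the behavioral statistics used to compare animals and to flag days
that deviate from an individual's healthy baseline.

## The method

A drinking event is inferred, not directly classified:

1. **Faucet localization.** The positions of up to two `Water-Faucet`
   detections with the highest confidence in the first 30 frames are fixed
   for the whole session as the stable spatial reference.
2. **Proximity scoring.** For every `Pig-Head` box with centroid
   $(x_c, y_c) = \left(\frac{x_1+x_2}{2}, \frac{y_1+y_2}{2}\right)$ the
   score against each faucet centroid is

   $$P = 1 - \frac{d}{d_\text{diag}}$$

   where $d$ is the Euclidean pixel distance between the centroids and
   $d_\text{diag}$ the frame diagonal. $P = 1$ means coincident centroids.
3. **Frame flagging.** A frame is flagged when any head–faucet pair reaches
   $P \ge 0.98$.
4. **Segmentation.** Maximal runs of flagged frames become events; runs
   shorter than 5 s are discarded as sniffing visits that cannot reflect
   substantial water intake.

Downstream, events are characterized per clock hour by *drinking power*
(event count × mean duration, in seconds), stratified into feeding-related
thirst hours {8, 9, 13, 14, 15} versus the remaining lights-on hours,
summarized per pig-day, and compared across animals with a Kruskal–Wallis
test (one-way ANOVA for reference, Shapiro–Wilk normality per group). An
illness-indicator rule flags days whose event count deviates from the
animal's own baseline median by more than *k* baseline standard deviations
(absolute mode) or by more than a fraction *r* of the baseline median
(relative mode).

A synthetic pen simulator (`penwatch.simulate`) generates full sessions —
bimodal diurnal visit schedules, a wandering head box, configurable detector
noise — so the entire pipeline is testable without video.

## Worked example

```python
import numpy as np
from penwatch import run_pipeline, frame_confusion, temporal_concordance
from penwatch.simulate import PenScene, ScheduleParams, simulate_session

scene = PenScene(fps=5.0, session_hours=2.0)
stream, truth, true_events = simulate_session(seed=1, scene=scene)
events = run_pipeline(stream)
print(len(true_events), len(events))          # 3 3
pred = np.zeros(stream.n_frames, dtype=bool)
for ev in events:
    pred[ev.start_frame:ev.end_frame] = True
print(frame_confusion(pred, truth).accuracy)  # 1.0
print(temporal_concordance(events, true_events).iou)  # 1.0
```

Three visits were scheduled in the two simulated morning hours; with the
noise-free detector the pipeline recovers all three, every frame is
classified correctly, and the detected drinking time coincides exactly with
the scheduled drinking time.

The analytics side, on the shipped reference measurements
(`penwatch.datasets`, an 18 pig-day study of three Göttingen minipigs):

```python
from penwatch import analytics, datasets
pt = analytics.power_table(datasets.load_hourly_reference())
print(round(pt.total_power_s, 1), round(pt.overall_mean_s, 2))  # 25359.9 41.44
h, p = analytics.kruskal_wallis(list(datasets.DAILY_EVENT_COUNTS.values()))
print(round(h, 2), round(p, 4))  # 11.8 0.0027
```

612 events carry a total drinking power of 25,359.9 s (mean 41.44 s per
event), and the three pigs' daily event counts differ significantly
(H = 11.80, p < 0.01).

The same workflows are available from the shell via the `penwatch` console
script (`simulate`, `detect-events`, `validate`, `summarize`, `power`,
`stats`, `illness`); every run writes a JSON provenance record with its
parameters and seed.

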