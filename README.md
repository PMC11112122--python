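# axotraffic

Quantitative analysis of axonal endolysosome trafficking and axon initial
segment (AIS) structure in cultured neurons, built for kymograph-based
live-imaging experiments (e.g. Lysotracker-labeled organelles moving
through axons in microfluidic chambers) and STED/confocal imaging of the
AIS. Because such experiments yield data that are rarely shareable at raw
scale, the package ships seeded synthetic-data generators that emulate
every input — particle tracks, kymographs, periodic membrane-skeleton
profiles, patch-bearing AIS images, marker intensity profiles, two-channel
particle intensities — so the entire pipeline is testable offline against
known ground truth.

## What it computes

**Track classification.** A track is the (frame, x) trace of one organelle
along an axon (0.175 µm/px, 1 s/frame, 180 frames by default). Each
inter-frame interval is scored *movement* iff |Δx| > 0.5 px. Maximal
moving stretches, split at displacement-sign reversals, of ≥ 5 intervals
are **runs** (distance Σ|Δx|·px, mean speed = distance/duration); maximal
non-moving stretches of ≥ 5 intervals are **pauses**; everything shorter
is **oscillation**. A track with no runs is **stationary**. A mobile
track's net displacement x_end − x_start is classified anterograde or
retrograde only when |Δx| ≥ 5 px (0.875 µm). Per-axon summaries (vesicles
per 10 µm, % stationary, mean pause, directional speeds/run lengths, net
displacement classes) feed nonparametric group statistics with n = axons.

**AIS structure.** MPS periodicity as the first prominent side peak of the
mean-subtracted, variance-normalized autocorrelation of longitudinal
F-actin STED profiles (30 nm px; the actin–spectrin lattice appears near
190 nm). F-actin patches by relative-threshold blob detection
(`pa_thre = 0.6` of the ROI dynamic range, `area_thre = 0.7` of the median
candidate area, 8-connectivity), reported as median patch area (px) and
patches per 10 µm. AIS length as the distance between the outermost
crossings of 0.33 × the smoothed, background-subtracted profile maximum.

**Colocalization.** Particles detected on one channel, integrated density
measured in both, summarized by OLS regression of B on A and Spearman's
rank correlation.

**Statistics.** D'Agostino–Pearson normality screen per group; t-test /
Mann–Whitney for two groups, ANOVA / Kruskal–Wallis plus Dunn's post-hoc
(implemented on the pooled ranking with tie correction) for three or more;
medians with distribution-free 95% CIs from binomial order statistics.

## Worked example

Simulate a wild-type-like cohort and push it through the classifier:

```python
import numpy as np
from axotraffic import AxonRecord, TrackMotionConfig, classify_cohort, wt_preset
from axotraffic.synthetic import simulate_tracks

rng = np.random.default_rng(1)
records = []
for i in range(100):
    tracks, _ = simulate_tracks(wt_preset(n_particles=20, seed=int(rng.integers(2**31))))
    records.append(AxonRecord(f"axon{i:03d}", tuple(tracks), kymo_length_um=111.1))
table, rejections = classify_cohort(records, TrackMotionConfig())
print(table[["pct_stationary", "mean_pause_s", "mean_speed_retro_um_s",
             "mean_run_distance_retro_um"]].median())
```

```
pct_stationary                55.000000
mean_pause_s                  16.529127
mean_speed_retro_um_s          0.487213
mean_run_distance_retro_um     8.740801
dtype: float64
```

The generative preset encodes 56% stationary organelles, 16.4 s median
pause, and retrograde runs of 8.71 µm at 0.48 µm/s; the cohort medians of
the per-axon means recover those parameters within sampling error — the
round trip that validates the classifier. The `analysis/` directory runs
the same workflow as numbered narrative scripts (simulation → track
metrics → AIS structure → colocalization → group report), writing tables
under `results/`.

A command-line interface mirrors the stages, e.g.:

```bash
axotraffic simulate tracks --n-axons 2 --seed 3 --out tracks/
axotraffic track-metrics --tracks tracks/ --out results/
axotraffic ais periodicity --profile mps.csv --out autocorr.csv
```

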