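# wormtrack

Multi-worm plate-video tracking and behavioral phenotyping for
*C. elegans* locomotion and pharmacological rescue assays.

Hyperactive-locomotion phenotypes — faster crawling, frequent reversals,
deeper body bends, coiled postures — are the workhorse readouts for worm
models of human neurological disease, and drug effects on them are
quantified against wild-type and solvent controls. `wormtrack` implements
that analysis chain as a tested, reusable library and CLI:

* **simulate** — a synthetic plate-video generator (dark undulating
  ~1 mm bodies on a light background, 3 frames/s, megapixel arena) with
  exact per-frame ground truth, so every downstream stage can be
  validated without recorded data;
* **segment** — Gaussian smoothing, Otsu/fixed thresholding, size-gated
  connected components with centroids, topological hole counts and
  skeleton midlines;
* **track** — centroid-proximity trajectory linking (Hungarian
  assignment, displacement gate `d_max`, gap tolerance) with logged
  quality gates in place of manual visual validation;
* **metrics** — per-track mean speed, reversals/min (trajectory bends
  > 50°), body bends/min (sign-alternating mid-body curvature extrema
  while moving), and coiled-time fraction (holes + low velocity);
* **assays** — paralysis time courses (percentage of animals still moving;
  log-rank test), convulsion proportions (Fisher's exact test with
  Bonferroni correction), egg-retention comparisons (t-test / ANOVA), and
  the percent-rescue statistic

  rescue % = (1 − Δ1/Δ2) · 100,  Δ1 = r_drug − r_wt,  Δ2 = r_nodrug − r_wt,

  where the `r` are reversals/min of the drug-treated mutant, untreated
  mutant and solvent-matched wild type: 0% means no drug effect, 100%
  means full normalization to wild type.

## Worked example

Simulate a 4-worm, 3-minute recording and analyze it end to end:

```python
from wormtrack.pipeline import PipelineConfig, run_pipeline
from wormtrack.simulate import SimulationConfig
from wormtrack.assays import percent_rescue

sim = SimulationConfig(arena_size=(768, 768), n_worms=4, duration=180.0, seed=1)
res = run_pipeline(PipelineConfig(simulate=sim, seed=1))
print(res.cohort.to_string(index=False))
gt = res.ground_truth
print("ground truth: %.1f um/s, %.2f rev/min, coil %.3f"
      % (gt.mean_speed(), gt.reversals_per_min(), gt.coil_fraction()))
print("rescue: %.1f%%" % percent_rescue(2.6, 4.4, 1.5).rescue_pct)
```

prints

```
            metric      mean      sem  n
        mean_speed 43.565320 2.842765  4
 reversals_per_min  2.504638 0.289211  4
body_bends_per_min 61.392881 0.315547  4
     coil_fraction  0.039352 0.019531  4
ground truth: 43.3 um/s, 2.50 rev/min, coil 0.041
rescue: 62.1%
```

The cohort table is the analysis output (mean ± SEM over accepted
tracks); the ground-truth line is what the simulator actually did, so the
recovery error is visible at a glance (speed within 1%, reversal rate
exact to two decimals here, coil fraction within half a percentage
point; bends/min ≈ 2 × 0.5 Hz × 60 = 60 by construction). The rescue call
says a drug that moves a mutant's reversal rate from 4.4 to 2.6/min,
against a wild-type rate of 1.5/min, rescues 62.1% of the defect.

The same pipeline runs from the shell:

```bash
wormtrack run --config config.json --out results/ --seed 1
wormtrack rescue --r-drug 2.6 --r-nodrug 4.4 --r-wt 1.5
wormtrack fixtures mutant_like --out fixtures/ --seed 0
```

Real recordings (multi-page TIFF or a PNG directory) enter at the
segmentation stage via `wormtrack segment` / `wormtrack.io.read_stack`.

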