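# Methods

## Overview

`wormtrack` quantifies *C. elegans* crawling behavior from plate videos the
way classical multi-worm trackers do, and pairs the locomotion readouts
with the statistics used in worm neuropharmacology assays. The chain is:

1. **simulate** — synthetic plate recordings with exact per-frame ground
   truth (the package's test bed; real recordings enter at the next stage);
2. **segment** — per-frame Gaussian smoothing, global thresholding,
   size-gated connected-component extraction, hole counting, skeleton
   midlines;
3. **track** — centroid-proximity linking of detections into per-worm
   trajectories with explicit quality gates;
4. **metrics** — per-track speed, reversals/min, body bends/min and
   coiled-time fraction, plus cohort summaries;
5. **assays** — paralysis time courses with the log-rank test, convulsion
   proportions with Fisher's exact test (Bonferroni corrected), egg-count
   group comparisons (t-test / one-way / two-way ANOVA), and the
   percent-rescue statistic.

## The synthetic worm and its behavior model

Each worm is a midline of 21 points with tangent angle
`theta(s) = heading + alpha * sin(phase + 2*pi*s/L)` along arc length
`s in [0, L]` — one undulation wavelength per body length `L`, with
`alpha = 2*pi*A/L` so the lateral half-amplitude is `A`. Points are laid
down by equal arc-length steps along the tangent, so spacing and total
length are exact by construction. A coiled worm replaces the sinusoid with
`theta(s) = heading + 2*pi*s/L`: a closed circle of circumference `L`,
which at the default body width necessarily encloses background — the
topological hole the coil detector relies on.

Behavior is a three-state machine (RUN, REVERSAL, COIL). From RUN,
reversals and coils arise as independent Poisson processes with the
configured per-minute rates; episode durations are exponential. Entering a
reversal flips the heading by an angle drawn uniformly in [120°, 180°]
(random side) — the published detection rule only requires the trajectory
bend to exceed 50°, and real escape reversals turn the animal most of the
way around; the exact distribution is a modeling choice, not a measured
one. A coiled worm is stationary with frozen undulation phase. Ground-truth
body bends are counted whenever the undulation phase crosses a multiple of
pi while the animal is moving — exactly the frames where the mid-body
curvature of the shape model is extremal — giving `2 * f` bends per second
at undulation frequency `f`.

### Key defaults (all configurable)

| parameter | default | why |
|---|---|---|
| arena | 1024 x 1280 px, 15 um/px | megapixel sensor; ~19 x 15 mm field of a 35 mm dish under moderate zoom |
| fps, duration | 3 frames/s, 600 s | matches the recording protocol the pipeline targets |
| body length / width | 1000 / 80 um | adult hermaphrodite |
| speed | 50 ± 10 um/s across worms | middle of the 29–76 um/s range typical of crawling on food |
| undulation | 0.5 Hz, A = 150 um | crawling body-wave frequency and amplitude (~0.3 L peak-to-peak) |
| reversal rate / duration | 3 /min, mean 2 s | plate-crawling order of magnitude |
| coil rate / duration | 0.5 /min, mean 10 s | a mild uncoordinated phenotype (~8% coiled time) |
| noise | sigma = 5 gray levels | clean transillumination imaging |
| contrast | worms 30 on background 200 | dark body on a light lawn |

### Rendering

Bodies are unions of disks of radius `width/2` swept along a densely
resampled midline. Two choices matter for measurement fidelity and are
deliberate:

* **Anti-aliased edges.** A pixel's value interpolates between worm and
  background according to its sub-pixel distance to the body boundary,
  emulating the partial-coverage gray edges produced by real optics.
  Hard-binary rendering makes downstream binary centroids inherit ~0.2 px
  of coherent quantization jitter (whole edge strips flip together as the
  body translates), which inflates measured speeds by >10% at slow crawl
  speeds and occasionally fires the 50° bend detector spuriously — an
  artifact of the renderer, not of the tracker under test.
* **Area-centroid alignment.** The swept body is asymmetric around the
  midline mean as the wave passes, so the body is drawn with its *area*
  centroid on the ground-truth trajectory (a measure-and-shift second
  rasterization pass). "Centroid" is then a well-defined observable: the
  segmented mask centroid tracks the ground-truth trajectory to ~0.15 px,
  and recovered speeds are unbiased to ~1%.

### Boundary handling

Worms are kept in view by smooth wall-avoidance steering: inside a margin
(default 2000 um) a worm heading outward turns toward the arena center at
a bounded rate (default 35°/s). The bound keeps the steering turn below
the 50° reversal threshold over the detector's measurement window, so wall
encounters never masquerade as reversals — a specular reflection (heading
flip) at the wall would be indistinguishable from a reversal and would
corrupt both the ground truth and the Poisson-rate property. Specular
reflection remains as a hard fallback at an inner margin (and as the
`boundary="reflect"` option), but with default parameters steering makes
it unreachable in practice.

### What the generator does not emulate

No worm–worm collision mechanics (overlapping animals simply merge into
one blob, which the size gate discards); no omega turns or 3-D postures;
no illumination gradients, lawn texture, or condensation artifacts; no
within-worm speed fluctuations beyond the mode switching. Passing the
recovery tests therefore shows the analysis chain is correct under clean
recording conditions, not that it is robust to every artifact of real
plates.

## Segmentation

Gaussian smoothing (sigma = 1 px) then a global threshold — Otsu per frame
by default, a fixed threshold for strict cross-frame reproducibility.
Objects are 8-connected components of the dark mask; holes are 4-connected
enclosed background components (the standard complementary pair). The
area gate defaults to [0.25 A, 4 A] around the expected worm area A, which
drops debris and merged multi-worm blobs. Midlines are skeletons pruned to
their longest geodesic path (double BFS); blobs with holes have no simple
midline and are flagged instead. Per-frame Otsu is reliable at the study's
noise level; at extreme noise (>~10% of dynamic range) it can admit
spurious blobs, and a fixed threshold is the better choice.

## Tracking

Per frame pair, detections are assigned to open tracks by minimum-cost
bipartite matching (Hungarian algorithm) on centroid distance, gated at
`d_max` (default three times the expected per-frame displacement,
`3 * speed_mean / fps`); among matchings restricted to feasible pairs the
assignment maximizes cardinality, then minimizes total displacement. The
default gap tolerance is 0 (consecutive frames only) and tracks shorter
than 30 frames (10 s) dissolve into an orphan pool, so every detection
ends in exactly one track or the orphan list. Manual visual validation is
replaced by logged gates: any implied speed above `max_speed`
(500 um/s default) or coverage below 90% rejects the track with a reason
code. Identity is deliberately not preserved through contact: collisions
merge blobs, the gate discards them, and tracks split.

## Behavioral metrics

* **Speed** — centroid displacement between consecutive linked frames
  times fps; cohort histograms pool per-step speeds.
* **Reversals** — at each point, direction vectors are displacement sums
  over `smooth_window` frames (default 3) before and after; steps shorter
  than `min_step` (default 0.2 px equivalent) carry no angle, suppressing
  sub-pixel jitter. An event fires once per contiguous excursion of the
  angle above 50°, at the frame of maximum angle; the rate is normalized
  by total observed track time. The detector is vectorized but is held
  equal, event for event, to a brute-force exhaustive scan in the tests.
* **Coiled fraction** — a frame is coiled iff the object has ≥1 hole and
  its centered-difference speed is at or below `v_coil`; the default
  cutoff is 10% of the cohort median track speed.
* **Body bends** — signed three-point curvature at the midpoint of the
  arc-length-resampled midline (span ±20% of body length, robust to
  skeleton pixel jitter); a bend is a curvature extremum of sign opposite
  to the previously counted bend, with magnitude above a small floor
  (5e-4 /um) to ignore numerically flat postures, counted only at frame
  speeds ≥ `v_move` (default 20% of cohort median); the rate is per minute
  of moving time.

Open normalization questions were resolved as follows and are exposed as
parameters: reversal rates use total observed time (a whole-track rate);
bend rates use moving time (the definition counts bends "while moving").

## Assay statistics

Paralysis data are right-censored event times; the moving-fraction curve
is the percentage of animals with event time beyond each timepoint, and
group curves are compared with the standard log-rank chi-square (1 df,
via lifelines). Convulsion-style 2x2 outcomes use the two-sided Fisher
exact test with an explicit Bonferroni multiplier, capped at 1. Egg-count
and rate comparisons offer a pooled-variance two-sample t-test, one-way
ANOVA with Bonferroni pairwise contrasts, and two-way ANOVA (statsmodels
OLS) for genotype x treatment designs.

**Percent rescue** is `(1 - D1/D2) * 100` with `D1 = r_drug - r_wt`,
`D2 = r_nodrug - r_wt`, where `r_wt` is always the wild-type rate under
the *matched solvent* (solvents measurably shift reversal rates, so the
interface requires the caller to supply solvent-matched values). The
bracket placement follows from the statistic's defining boundary
behavior: 0% when the drug changes nothing (`r_drug = r_nodrug`), 100%
at full normalization (`r_drug = r_wt`). It is undefined when the
untreated mutant already equals wild type (`D2 = 0`), is invariant under
shifting or positively scaling all three rates, and is strictly
decreasing in `r_drug` whenever `D2 > 0`.

## Numerical and testing choices

Randomness flows through one seeded `numpy.random.Generator`; identical
configuration and seed give bit-identical frames, tables, and manifests.
Matching ties are broken deterministically (lower object id). Degenerate
inputs are rejected with explicit errors: length-1 tracks for speed,
tracks shorter than the angle window, empty cohorts, all-constant groups,
`D2 = 0` rescue inputs.

Validation runs at the following problem sizes: parameter recovery on one
20-worm, 10-min, 3-fps recording at full sensor resolution; tracking
purity on a 3-worm, 5-min recording; reversal-detector oracle equivalence
on 100 single-worm trajectories; log-rank null calibration on 1000
replicates of 20 + 20 animals; phenotype discrimination on 20 repetitions
of 20-vs-20-worm cohorts at trajectory level. Trajectory-level checks use
ground-truth tracks directly (`tracks_from_ground_truth`), which isolates
the metric stage from imaging; image-level checks run the full chain.

## Known limitations

* Identity is lost at every worm–worm contact by design; per-worm rates
  on crowded plates are slightly diluted by short merged-blob tracks.
* Image-derived body-bend rates at the default optics are noisier than
  trajectory-level ones (the skeleton of a ~5 px-wide body has pixel-level
  curvature jitter); the bend definition is validated against analytic
  midlines.
* Per-frame Otsu assumes worms are present and dark; empty frames yield
  an empty mask only because a zero-range frame is special-cased.
* The measured mean of `|displacement|` is upward-biased by centroid
  noise at very slow speeds; with the default optics this bias is ~1%.
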