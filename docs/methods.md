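# Methods note

This note records the model underlying `ranevs`, the default parameter
values with units and rationale, what the synthetic-data generator does and
does not emulate, the numerical choices that matter for reproducibility,
and the problem sizes used by the validation suite.

## Task and measurement model

A RAN run presents 36 items in a 4 × 9 grid; the participant names them
serially (row-major). Four stimulus types (color, object, number, letter)
are grouped into two analysis conditions: **symbolic** (numbers + letters)
and **non-symbolic** (colors + objects). Each participant completes two
runs per stimulus type.

Two synchronized records describe a run:

1. a **gaze trace**: binocular samples at a nominal 60 Hz, each eye with a
   validity flag. The binocular point is the average of the two eyes and
   exists only when *both* are valid; no interpolation or gap-filling is
   performed.
2. a **voice track**: one event per named item with onset/offset times and
   optional error tags (substitution, omission, repetition,
   self-correction). Omissions carry no interval.

### Geometry

Pixels convert to visual angle through the physical screen description
(default 1280 × 1024 px, 43.3 × 34.6 cm, viewed at 57 cm — at that distance
1 cm on screen subtends almost exactly 1°). The angle between two screen
points is `2·atan(chord/2D)` with the chord measured in cm via the pixel
pitch. AOIs are half-open rectangles `[left,right) × [top,bottom)`
extending from each item's center to the midpoints toward its neighbours
(half the item spacing at grid edges), so the 36 AOIs partition the grid
exactly.

### Fixation detection (I-VT)

- Sample velocity: central difference over the neighbouring samples
  (i−1, i+1), one-sided at trace edges and next to invalid samples;
  velocity is undefined (treated as saccade) where no valid neighbour
  exists.
- Classification threshold: samples strictly below **35°/s** are fixation
  candidates.
- Merging: consecutive candidate groups are merged when separated by
  ≤ **100 ms** *and* their centroids lie within **0.5°**.
- Duration filter: merged fixations shorter than **100 ms** are discarded
  (boundary inclusive: exactly 100 ms is kept).

These four values are the standard I-VT defaults for 60 Hz remote trackers
and are exposed in `IVTParams`.

### Eye-voice span (EVS)

At each vocal onset the fixated serial index is read from the fixation
sequence, carrying the most recent fixation forward through saccades; the
EVS sample is `fixated_index − spoken_index` (items). Onsets on omitted
items or before any on-array fixation yield no sample. The run's EVS is
the mean over samples on positionally retained items.

### Scanpath metrics

On the AOI sequence of retained fixations: **perseverations** are
adjacent equal pairs, **regressions** are backward transitions to an item
already visited earlier in the sequence, and **refixations** are their
sum. `total_fixations` counts retained fixations before any pooling.

### Quality control and aggregation

A run is excluded (reasons accumulate) for:

| rule | threshold |
| --- | --- |
| binocular track loss | > 35 % of samples |
| fixation-free gap (incl. trace start/end) | > 10 s |
| fixation count, symbolic | outside 15–50 |
| fixation count, non-symbolic | outside 20–55 |
| classification failure | fixation detection impossible |

Eye-movement metrics (EVS, scanpath counts) drop the first **2** and last
**4** serial positions (row-start mistargeting and end-of-array return
sweeps); naming time and error counts keep all 36 items. Per-participant
condition summaries are two-stage means — runs within a stimulus type
first, then the two stimulus types of the condition — so an excluded run
cannot let one stimulus type dominate.

### Statistics

Per condition and response, a diagnosis × culture linear model with
treatment coding (control and US as reference levels) and covariates sex
and age (IQ added for naming time and errors). With one observation per
participant this is OLS; with repeated observations a random-intercept
mixed model (ML) is used and t-tests use a residual-df approximation. A
likelihood-ratio statistic for dropping the interaction is reported;
inference proceeds with the interaction retained. Families of p-values are
adjusted by Benjamini-Hochberg (FDR 0.10 nominal). Cell contrasts use
model-predicted cell means at sample-mean covariates with studentized-range
(Tukey) p-values. Auxiliary tests: Mann-Whitney U (exact enumeration when
n₁+n₂ ≤ 12, valid under ties; tie-corrected normal approximation with
continuity correction otherwise), partial Pearson correlation via
residualization (df = n − 2 − k), and Pearson chi-squared without
continuity correction for exclusion proportions.

## Synthetic-data generator

The simulator produces gaze + voice records whose scored metrics are known
by construction, which makes parameter recovery the validation surface.

Per item it draws a lognormal articulation duration (mean 0.55 s, CV 0.25;
symbolic items scaled by 0.6; floor 0.2 s) separated by 0.12 s pauses. The
eyes occupy item `i + lead` (default lead 1) for the full articulation of
item `i`, arriving 0.08 s before the vocal onset. With probability
`p_perseveration` (default 0.15) an extra 0.18 s fixation on the same item
is inserted; with probability `p_regression` (default 0.12) an extra
fixation on a uniformly drawn previously visited retained item within 5
items back. Injections occur only when the inter-onset window has
capacity for the extra fixations, and the generator records *eligibility*
tallies so injection probabilities can be estimated without censoring
bias. Samples get isotropic Gaussian noise (default 0.2°), independent
per-sample track loss (default 5 %), and the two eyes are emitted at ±2 px
around the binocular point so strict averaging recovers it exactly.
Naming errors are tagged with probability 0.03 per item.

Deliberately **not** emulated: saccade kinematics (jumps are
instantaneous, which is sufficient because a 1.7° displacement at 60 Hz is
far above the 35°/s threshold), smooth pursuit, drift, blink dynamics
beyond validity flags, articulatory acoustics, and any culture-specific
calibration. Demographic covariates (sex, age, IQ) are generated as pure
nuisance variables with no effect on the response, so covariate-adjustment
code paths are exercised without confounding the ground truth.

At the default noise level (0.2°) the detection chain occasionally splits
or drops an injected 0.18 s fixation when track loss lands inside it; over
200 default runs the induced bias is < 0.005 in either refixation rate and
< 0.01 items in EVS — well inside the validation bands below. Exact
count-recovery checks therefore use low-noise (≤ 0.05°), zero-loss
settings where recovery is deterministic.

## Numerical choices

- All randomness flows through `numpy.random.Generator` seeded from
  explicit integers; cohorts derive per-run seeds from
  `numpy.random.SeedSequence` spawning, so any run is reproducible in
  isolation and child seeds stay below 2³¹.
- Fixation merging accumulates sums rather than re-averaging, so centroids
  are exact means of member samples.
- AOI lookup uses `searchsorted` on the shared column/row edges; the
  half-open convention makes assignment unique on boundaries.
- Boundary comparisons are inclusive where the rule says "at most"
  (merge gap ≤ 100 ms, merge angle ≤ 0.5°, duration ≥ 100 ms, count bounds
  inclusive) and strict where it says "more than" (track loss > 35 %,
  gap > 10 s, velocity < 35°/s for fixations).
- OLS, mixed models, BH adjustment, studentized-range and chi-squared
  distributions delegate to `statsmodels`/`scipy`; the package-specific
  logic (designs, contrasts, exact Mann-Whitney enumeration,
  residualization) is implemented here and cross-checked against oracles.

## Validation problem sizes

Sizes were chosen so the full test suite runs in a few minutes on one CPU
while keeping every statistical assertion well-powered; they are the
package's own choices and can be scaled up freely.

- Oracle-equivalence suites: ≥ 1000 random instances per operation.
- End-to-end recovery: 100 default-parameter runs; acceptance bands
  ±0.1 items (EVS) and ±0.02 (refixation probabilities, estimated as
  detected counts over eligibility tallies).
- Effect-sign recovery: injected +0.08 regression probability for ASD
  groups; 40 replicate cohorts at n = 12/group in the test suite and 100
  replicates at n = 16/group in `scripts/acceptance.py`; required sign
  accuracy ≥ 95 %.
- Null calibration: 400 (tests) / 1000 (script) metrics-level replicate
  tables at n = 12/group; the α = 0.05 rejection rate must fall inside the
  central 99 % binomial interval.
- Threshold sweeps: bisection to < 10⁻⁶ resolution for continuous
  thresholds, integer sweeps for counts.

## Limitations

- The simulator's gaze lead is constant at fixation granularity; real EVS
  varies item to item, so only the mean lead is a recovery target.
- The mixed-model t-tests use a residual-df approximation rather than
  Satterthwaite df; with the balanced designs used here the difference is
  negligible, but very unbalanced panels would warrant a dedicated df
  method.
- Group-level findings from human studies are not reproducible from
  synthetic data; the statistics layer is validated for calibration and
  recovery, not for replicating any published estimate.
- The TextGrid reader covers the common long-format interval-tier files it
  writes; exotic TextGrid variants (short format, point tiers) are out of
  scope.
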