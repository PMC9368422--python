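# Methods

This note documents the models, conventions and numerical choices behind
`affectgait`, and what the synthetic experiments do and do not demonstrate.

## Metric-to-PAD mapping

The pipeline starts at the five vendor performance metrics, not raw EEG.
The published mapping from such metrics to PAD is not reproduced in the
evaluation literature we target, so the default here is an explicit,
documented stand-in:

    pleasure  = 0.5 + 0.5 * (excitement  - frustration)
    arousal   = 0.5 + 0.5 * (engagement  - meditation)
    dominance = 1.0 - boredom

Each PAD row reads a disjoint subset of the metrics, which makes the map
midpoint-centred (all metrics at 0.5 give PAD (0.5, 0.5, 0.5)),
sign-interpretable, and — crucially for validation — *exactly invertible on
the whole PAD cube*: the minimum-norm affine inverse centred at the metric
midpoint stays inside [0,1]^5 for every PAD target. A dominance row that
reuses excitement (e.g. `0.5 + 0.5*(excitement - boredom)`) was rejected
because it constrains `pleasure - dominance` to [−0.5, 0.5], leaving region
triples such as (P=5, D=1) with no metric preimage and breaking the
round-trip identity the generator and tests rely on. The 3×5 weight matrix
and offsets are fully configurable (`MappingConfig`); any full-row-rank
matrix whose centred pseudo-inverse respects the metric box is accepted by
`invert_pad_array`, and anything else raises `MappingNotInvertibleError`.

Discretization uses equal-width, left-closed bins: region
`min(floor(5·v) + 1, 5)`, so 0.2 falls in region 2 and 1.0 in region 5.
Region labels default to the SAM wording (arousal: calm, dull, neutral,
wide-awake, excited; pleasure region 2 "unsatisfied", dominance region 1
"powerlessness"); names not attested in the SAM literature are placeholders
and configurable.

## Intervalization and matching

Annotators mark only perceived changes, so events are change points: each
event's triple holds until the next event (step-hold), yielding half-open
intervals that tile [t_first, session_end). Matching counts every
machine × human interval pair with positive overlap as one match — no
minimum-overlap threshold by default (configurable), no duration weighting
by default (a duration-weighted confusion mode exists). Touching endpoints
do not match. With several reviewers the pooled match count therefore far
exceeds either side's event count, which is the observed regime for this
kind of panel evaluation. Matching is a linear two-pointer sweep; tests
check it against an independent elementary-segment sweep-line oracle and
verify overlap conservation.

## Classification reports

Conventions chosen to match standard imbalanced multi-class reporting:

- zero-division → 0 for precision, recall and F1 (empty regions print 0);
- accuracy = trace/total, which equals support-weighted recall (asserted);
- weighted averages are support-weighted over all rows;
- **macro averages run over the observed label set** — the union of labels
  with actual or predicted mass — exactly as scikit-learn does when labels
  are not fixed. This is forced by the published tables: their macro rows
  divide by 5, 4 and 3 labels respectively for pleasure, arousal and
  dominance. An explicit `labels=` argument recovers the fixed-set
  convention when wanted.

`confusion_from_report_rows` inverts the report arithmetic
(diag = recall·support, colsum = diag/precision, both rounded to integers)
to rebuild a consistent integer matrix from printed rows. The printed rows
do not reveal how many labels the original evaluation observed, but the
macro precision cell does (count = Σprecision / macro_precision); the
observed set is extended with the smallest unused labels and leftover
off-diagonal mass is spread evenly across them (a balanced-swap repair
handles rare transport dead ends). Reports carry full double precision;
table output formats to 6 decimals.

## Session metrics

Timing summaries use the sample (n−1) standard deviation and half-up
rounding to whole seconds — both forced by reproducing the published
summary cells exactly (the population SD gives a different integer for the
session column; banker's rounding breaks the half-integer medians).
Efficiency is the fraction of samples flagged as active effort; flags are
input (telemetry is out of scope), with a documented default threshold of
0.5 for continuous effort series. The rotation schedule shifts the video
list left by (reviewer − 1), a Latin square when reviewers = videos.

## Synthetic session generator

The generator defines the study-like conditions under which the pipeline is
validated. No distributional description of real metric streams is
available to us, so all of the following are explicit stand-ins with known
ground truth — passing tests demonstrate correct *pipeline arithmetic and
parameter recovery*, not fidelity to real EEG.

**Truth process.** Per dimension, a continuous-time Markov jump process on
regions 1..5 with jump rate i→j equal to λ·π_j (j ≠ i), where π is the
configured stationary vector. This chain is reversible with stationary
distribution exactly π, successive regions always differ, and dwell times
are exponential; λ = 1/(mean_dwell·(1 − Σπ²)) makes the long-run mean time
between changes equal `mean_dwell_s` (per-region dwell means then differ —
with forced jumps and a single dwell mean the time-occupancy could not
equal a general π). A one-hot π yields a single interval. Change points are
quantized up to the sampling grid (≥ 1 sample dwell) so the sampled metric
stream carries the complete trajectory; without this, machine change
detection snaps to the grid while human events sit at off-grid times,
producing sliver matches that cap accuracy strictly below 1 even for
perfect reviewers.

**Metrics.** At each sample a PAD vector is drawn uniformly inside the true
region's bin (kept 1e-9 off the edges for float safety), inverted through
the mapping, then Gaussian noise (`metric_noise_sd`) is added and values
are clipped to [0,1]. With zero noise, map→discretize recovers the true
region at every sample; recovery degrades monotonically with noise.

**Reviewers.** Each reviewer emits a bootstrap event at t = 0 and detects
each true change with probability `p_detect`; timestamps get Gaussian
jitter truncated to preserve the stream's order, and each dimension's label
is correct with probability `p_agree`, otherwise an adjacent region
*distinct* from the truth (1→2, 5→4, else ±1 equiprobably — ordinal scales
confuse neighbours). `p_agree` applies to the bootstrap event too;
exempting it, or letting boundary "errors" clamp back onto the true label,
would bias measured agreement above `p_agree`.

**Defaults** emulate a plausible therapy cohort: 1959 s sessions (the
published mean duration) at 1 Hz, mean dwell 60 s (tens of perceivable
affect changes per session), skewed occupancy concentrated on "unsatisfied"
pleasure (0.62 on region 2), "wide-awake" arousal (0.62 on region 4) and
low dominance (0.90 on region 2), 8 reviewers, p_detect 0.8, p_agree 0.85,
jitter 2 s, metric noise 0.05. One integer seed drives named substreams
(truth / metrics / reviewers, per session index), so a fixed (seed, config)
pair is byte-reproducible.

**Agreement-recovery experiments** use a label-noise-only cohort
(p_detect = 1, jitter = 0, noise = 0, varying p_agree): under those
conditions machine and human breakpoints coincide, matches pair one-to-one,
and pipeline-measured accuracy is an unbiased estimate of p_agree — the
experiment recovers 0.7/0.8/0.9 within ±0.02 over 8 reviewers × 50
sessions (≈ 39,000 matches per setting; Monte-Carlo SE ≈ 0.002). Detection
misses and jitter are deliberately excluded there because each provably
shifts unweighted-match accuracy away from p_agree (stale-label spans and
boundary slivers); they are separate error channels, exercised by the
default configuration and by dedicated unit tests.

## Known limitations

- The default metric→PAD matrix is a stand-in; absolute PAD values from
  real headsets require a calibrated mapping.
- The generator does not simulate raw EEG, electrode contact, sensor
  displacement or per-patient idiosyncrasies; synthetic agreement numbers
  say nothing about real-world EEG validity.
- Study-level raw counts (total machine/human events, pooled match counts)
  and the with/without-VR efficiency contrast depend on recordings that are
  not distributed; the package implements the operations and validates
  them synthetically instead of reproducing those observations.
- Reports assume a fixed 1..5 region universe per dimension.
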