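# Methods

This note documents the models and procedures implemented in `tsevents`,
the parameters that matter, the conventions chosen where the design was
genuinely open, and what the synthetic benchmarks do and do not show.

## Signals, events and the subject tree

A signal is a fixed-rate sequence of numeric samples (default sampling
period 10 ms; EEG series default to 4000 samples, stabilometric pressure
traces to 1000).  An **event** is a typed region `[start, end)` (0-based,
half-open) characterised by its duration in milliseconds, a magnitude
(peak amplitude above baseline for EEG waves; mean suprathreshold
intensity for falls) and an anchor — the sample index of the extremum.
The invariant `duration_ms = (end − start) × sampling_period_ms` is
enforced everywhere; all sample↔time conversion goes through the sampling
period.

Subjects are hierarchical records: one *register* root, *measurements*
(an examination), *conditions* (the circumstances it was taken under),
and leaves that are either time series or single quantitative/qualitative
values.  One canonical XML schema carries this tree; any other dialect
must be converted upstream.

## Preprocessing

Recordings are noisy at their edges (patient and supervisor out of
phase); `trim_edges` cuts the lead-in/lead-out, chosen manually or by
protocol — deliberately not automated, mirroring how the first screening
filter works in practice.  `clean_series` then *omits* (never
interpolates) missing values — a configurable sentinel such as a pressure
reading of exactly 0 — and values outside a domain-dependent plausible
range.  A series is valid when at least 70% of its samples survive; the
comparison is inclusive (exactly 70% is valid).  Invalid series are
excluded from modelling.  Because omission shortens the series, event
timestamps always live in the cleaned index space.  If every sample is
dropped the result carries `series=None` with `valid=False` rather than
raising, so cohort-level screening loops stay simple.

## Event definitions and detection

Two trigger families:

* **Relative amplitude** (EEG paroxysms).  The mean-centred signal is
  segmented into *waves* at its zero crossings; each maximal
  constant-sign run is one wave carrying its extremum.  Samples within
  `1e-9 × max|x|` of zero inherit the sign of the next nonzero sample, so
  a sampled sinusoid whose grid hits the crossings exactly still splits
  into equal half-cycles.  A wave becomes an event when its peak
  deviation exceeds `k ×` a baseline scale and its period lies in the
  definition's band (spike 20–70 ms, sharp wave 70–200 ms, both ends
  inclusive).  The baseline scale is, by default, the median absolute
  deviation scaled by 1.4826 (comparable to a Gaussian σ and robust to
  the events themselves); the plain standard deviation is available.
  `k` defaults to 3.  A *spicule* — sharp wave with an abrupt polarity
  change — additionally requires an adjacent wave of opposite sign whose
  own peak exceeds `k′ ×` the scale (`k′ = k/2` by default).  Since waves
  alternate sign by construction, adjacency already encodes "no
  intervening sub-baseline wave".
* **Absolute threshold** (stabilometric falls).  Each maximal run of
  samples strictly above ∂ is one event.  `merge_gap_ms` bridges brief
  sub-threshold dips (sensor chatter) and `min_duration_ms` suppresses
  spurious blips; both default to 0 and are set per rule.

Definitions are written in a small keyword rule syntax (one block per
event type; see `events.py`), parsed with line-numbered diagnostics.

The rule sets shipped with the synthetic presets encode an operating-point
choice: the EEG rule uses `k = 4` because at 4000 samples per series a
3σ wave-peak test admits a handful of chance exceedances per series
(Gaussian tail × ~10³ waves) whereas 4σ keeps the expected false-alarm
count well below one; the fall rule uses ∂ = 50, a 100 ms minimum
duration and a 50 ms merge gap so that low-intensity falls whose plateau
grazes the threshold are not fragmented.

## Agreement with expert annotation

Detector output is compared with a reference annotation by a one-to-one
matching: a pair must share the event type and overlap by at least half
of the shorter event (the 0.5 is configurable; some matching criterion
must be chosen, and overlap of the shorter event is insensitive to
boundary jitter).  The maximum number of simultaneously matchable pairs
is found as an assignment problem, so the count is order-invariant.  The
agreement statistic `SIM = 2·n_match / (n_exp + n_det)` is Dice-style:
symmetric, 1 exactly on identical sets, 0 on disjoint ones.  Two empty
sets agree vacuously (the 0/0 case is defined as 1).  Display follows the
conventions of the domain literature: SIM truncated to three decimals,
confusion-matrix indicators (precision, recall, specificity, accuracy)
as percentages rounded to one decimal, with zero-denominator metrics
reported as undefined rather than 0.

## Similarity

Event similarity is a hard type gate (different types → 0) followed by a
weighted mean over the three features of `max(0, 1 − |Δf| / range_f)`.
The functional form was chosen for interpretability and because, with 0/1
event weights, the series score reduces exactly to the Dice agreement
statistic — the two layers of the package measure the same thing at
different granularity.  Feature ranges default to the 5–95% inter-quantile
spread of the observed events (robust both to the heavy right tail of
duration distributions and to contaminating outliers); weights default to
equal thirds, with `anchor_weight` exposed because event *timing* is
meaningful in some domains and free in others (0 is the right choice for
falls, and for any data whose event times are unstructured).

Series similarity is the maximum-weight one-to-one matching between two
event sets, scored `2·Σw / (|a| + |b|)` so unmatched events on either
side are penalised symmetrically.  Subject similarity walks two
structurally identical trees: series leaves score by series similarity,
quantitative leaves by `max(0, 1 − |a−b|/range)`, qualitative leaves by
equality; internal nodes aggregate children by a weighted mean (equal by
default).  The annotated tree is returned so a reader can see *where* two
subjects differ.  All similarities are symmetric, reflexive and bounded
in [0, 1].

## Reference models

All events of the retained training series are pooled and clustered by
average-linkage agglomerative clustering on `1 − event similarity`
(cross-type distances are set far above any cut, so types never merge),
cut at `tau_m = 0.3`.  A cluster qualifies when its *support* — the
fraction of training series contributing at least one member — reaches
`min_support = 0.5` ("often found" made concrete).  A qualifying cluster
found on average *m* times per series (`m = round(cluster_size /
n_series)`) contributes its *m* most central members, the first being the
medoid.  Representatives are real observed events, so every model row is
something a specialist can look up in a recording, and the archetype's
event count matches a typical series of its class — a subject and a model
then have comparable masses under the Dice-style matching score.  With
one row per cluster regardless of multiplicity, a model with more rows
dominates the matching score for every subject (each extra row adds
matched weight while the denominator grows by one), which measurably
breaks classification.

Model-to-subject similarity treats the model as an archetypal patient:
its event set is compared against *each* series leaf of the subject and
the leaf scores aggregate by the equal-weight tree mean, exactly as in a
subject-to-subject comparison.

## Outlier screening

Before a model is built, the class's pairwise subject-similarity matrix
is screened by four criteria that mimic how a person eyeballing the
matrix spots the odd one out:

* **C1** — the subject's mean similarity to its class is more than
  `z = 2` standard deviations below the average row mean;
* **C2** — its best similarity is below the isolation threshold 0.5;
* **C3** — it sits in a dendrogram cluster (average linkage on
  1 − similarity, cut 0.5) smaller than 2, i.e. alone;
* **C4** — removing it tightens its own cluster's mean pairwise
  similarity by more than δ = 0.05.

A subject is an outlier when at least 2 criteria fire.  Two conventions
make C4 total: the cohesion of a singleton set is vacuously 1 (the same
convention as empty-vs-empty similarity), so removing one member of a
pair cluster "tightens" it to 1; and for a subject already alone in its
cluster the criterion falls back to cohort-level cohesion (does removing
it tighten the cohort as a whole?).  Screening similarity uses
class-internal feature scaling — typicality is a class-relative question
— while model building and prediction share the global training scaling.

Known limitation: a *pair* of outliers with nearly identical
characteristics corroborate each other (mutual similarity ≈ 1) and can
evade the vote, since only C1 fires for them.  This is intrinsic to the
criteria, not to their thresholds.

## Classification and validation

Training builds one reference model per class after screening (classes
with fewer than three subjects skip screening; at least two retained
subjects are required).  A new subject receives the class of its most
similar model; exact ties go to the lexicographically smallest label and
are flagged.  Validation is stratified 10-fold cross-validation
(90%/10%), shuffled with a logged seed; screening happens inside each
training fold only, never on held-out subjects, to avoid leakage.
Per-class accuracies are pooled over folds (per-fold values are
recoverable from the assignment table).

## Synthetic cohorts

The generator emulates the event statistics of the two study cohorts:

| class      | events/series | duration (ms) | magnitude | series |
|------------|---------------|---------------|-----------|--------|
| epileptic  | 9.47          | 195           | 78        | 1 × 4000 samples |
| healthy    | 5.49          | 56            | 54        | 1 × 4000 |
| basketball | 3.37          | 754           | 107       | 12 × 1000 |
| skating    | 1.45          | 346           | 83        | 12 × 1000 |

Counts are Poisson (truncated at ~55% series occupancy, since a finite
trial cannot hold unboundedly many non-overlapping events), durations
lognormal (positivity), magnitudes normal; standard deviations default to
20% of the mean because only means are available for the reference
cohorts.  EEG events are half-sine deflections of random polarity on
Gaussian noise (σ = 10); falls are suprathreshold plateaus on near-zero
noise (σ = 5).  Stabilometric subjects carry 12 series (4 trials × 3
repetitions, the acquisition protocol of the posturographic test).  Every
planted event is recorded with exact indices, and the whole cohort is a
deterministic function of the seed.

Outlier subjects shift their duration and magnitude means by a chosen
number of scale units (5σ in the benchmarks) with independent random
signs per subject; magnitude reflects at zero since amplitude is
physical.  The manifest of injected outliers is recorded.

What passing the synthetic benchmarks shows — and what it does not: the
generator produces feature-separable classes with independent events on
stationary noise.  Real EEG has coloured spectra, artefacts, multichannel
structure and within-subject correlation; real posturography has sway
dynamics.  Results on synthetic cohorts validate the machinery
(detection, matching, clustering, screening, validation protocol), not
clinical performance.

## Problem sizes and numerics

The shipped benchmarks use 20 subjects/class × 5 seeds for
cross-validation, 10/class for loop closure, and 20/class with 10%
injected outliers for screening — sizes at which every stage's behaviour
is already stable while the whole suite runs in seconds.  Assignment
problems are solved exactly (Hungarian algorithm) and verified against
exhaustive enumeration on all instances with ≤ 6 events per side.
Display truncation adds `1e-9` before flooring to absorb binary float
fuzz.  Ties in medoid selection break by earliest start index, then
lexicographic type; prediction ties within `1e-12` are flagged.
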