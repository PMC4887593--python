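# tsevents

Event-centric mining of biomedical time series.

In many clinical signals the information specialists care about is
concentrated in short regions — *events* — rather than spread over the whole
trace: paroxysmal abnormalities in an EEG (spike waves with a 20–70 ms
period, sharp waves at 70–200 ms, spicules with an abrupt polarity change),
or *falls* in a posturographic unilateral-stance test (intervals where the
raised-foot sensor pressure exceeds a threshold ∂).  Whole-series distances
(Fourier, wavelets, DTW) average over the uninteresting parts; `tsevents`
instead works event-first, for physicians and sports-medicine researchers
who want classifiers whose internals they can read.

The pipeline, end to end:

1. **Event definitions & detection** — declarative rules (relative-amplitude
   waves or absolute-threshold runs) map a cleaned series
   `TS = {TS_t, t = 1..N}` to a set of events characterised by duration and
   magnitude (amplitude / intensity).
2. **Agreement with experts** — detector output is scored against expert
   annotations with the Dice-style statistic

   `SIM = 2 · #Ev_match / (#Ev_exp + #Ev_detected)  ∈ [0, 1]`.

3. **Similarity** — two series are compared through a maximum-weight
   one-to-one matching of their event sets; two subjects through their
   shared register → measurement → condition tree.
4. **Reference models** — per class `C_i`, pooled training events are
   clustered (average linkage on 1 − similarity); frequent clusters
   contribute representative observed events to a prototype `M_i`, after
   outlying subjects are screened out by a four-criteria vote on the
   pairwise similarity matrix.
5. **Classification** — a new subject `P_new` gets the class
   `C_j = argmax_i similarity(P_new, M_i)`, evaluated by stratified 10-fold
   cross-validation.

A seed-deterministic synthetic generator plants ground-truth events with
the per-class count/duration/magnitude statistics of the two study domains,
so every stage is testable without any real recordings.

## Worked example

```python
import tsevents as tv

# agreement metric on annotated counts
counts = tv.EvaluationCounts(n_exp=1446, n_lang=1496, n_match=1412)
print("SIM =", round(tv.sim_exp_lang(counts), 4))      # SIM = 0.9599

# two-class synthetic EEG cohort -> detect -> fit -> cross-validate
cohort = tv.generate_cohort(
    [tv.eeg_epileptic_spec(), tv.eeg_healthy_spec()], n_per_class=20, seed=0
)
subjects = tv.annotate_cohort(cohort, tv.default_definitions("eeg"))
labels = [s.class_label for s in subjects]

results = tv.EventClassifier(subjects, labels).fit()
print(results.summary())
print(tv.cross_validate(subjects, labels, k=10, seed=0).summary())
```

which prints (abridged):

```
class 'epileptic': 9 model event(s) from 20 subjects
 #Event     Type  Duration (ms)  Magnitude  #Timestamp  Support  Cluster size
      1 paroxysm          170.0  84.969605         903     0.95            87
      ...
class 'healthy': 6 model event(s) from 19 subjects; outliers removed: healthy-003
 #Event     Type  Duration (ms)  Magnitude  #Timestamp  Support  Cluster size
      1 paroxysm           60.0  55.360645        1589      1.0           109
      ...
10-fold cross-validation (seed 0)
--------------------------------------------
Class             Accuracy
epileptic           95.00%
healthy            100.00%
overall             97.50%
```

Each model row is a real observed event (the most central members of a
frequent cluster): its duration, magnitude, anchor timestamp, the fraction
of training series supporting the cluster, and the cluster size.  The
epileptic prototype carries more, longer, larger events than the healthy
one — exactly the structure a reader can check against domain knowledge.
The CV table reports pooled per-class and overall accuracy.

A `tsevents` command-line tool wraps the same functions:
`simulate`, `detect`, `evaluate`, `compare`, `model`, `classify`, `cv` —
all emitting JSON and logging their seed.

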