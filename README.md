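# transferkit

Evaluation and detection of wheelchair transfers from a single chest-mounted
triaxial accelerometer.

Wheelchair users transfer between their chair and other surfaces (bed,
toilet, car seat) many times a day. Transfer technique matters: a good
*head-hip relationship* (leaning the head forward and down to unload the
hips) and a *smooth landing* reduce upper-limb load and fall risk, but
technique is normally assessed by a clinician watching the transfer.
`transferkit` implements a wearable-sensor alternative for researchers and
rehabilitation engineers: one accelerometer taped to the sternum (25 Hz,
±16 g, X vertical / Y lateral / Z frontal), two machine-learning pipelines,
and a synthetic session generator so the whole chain can be developed and
tested without recorded patient data.

**Quality pipeline** — given seat-off and landing timestamps, three phase
windows are cut (±0.75 s around seat-off, seat-off −0.5 s to landing +0.5 s,
±0.75 s around landing) and scored:

* head-hip: extrema/ranges of the frontal acceleration and its jerk and of
  the frontal-downward composite `x − z` (a quick deep forward lean produces
  a sharp frontal dip);
* smooth landing: max/mean/RMS/range statistics of vertical and total
  acceleration (a hard landing is a sharp vertical spike);
* controlled flight: movement-smoothness metrics — spectral arc length
  (SPARC) and dimensionless jerk of the reconstructed speed profile
  (computed and exportable, but not trained by default: labels for this item
  are typically too imbalanced).

**Detection pipeline** — 25-sample windows (1 s) with hop 12 are labeled by
overlap with annotated transfer intervals, and 59 features are computed per
window: for each of X, Y, Z and the total-acceleration vector, SD, variance,
five percentiles, IQR, 10th–90th percentile range, lag-one autocorrelation
over a 10 s context, three Daubechies-2 wavelet-coefficient norms, and
sample entropy (m = 2, r = 0.3 SD); plus the three axis cross-correlations
(14 × 4 + 3 = 59).

Both pipelines share correlation-based feature subset selection (CFS merit
`k·r̄_cf / √(k + k(k−1)·r̄_ff)` with best-first search), per-subject 1:1
undersampling for the imbalanced detection task, and leave-one-subject-out
(LOSO) cross-validation over four classifier families (linear SVM, random
forest, Gaussian naive Bayes, multinomial logistic regression).

## Worked example

Simulate a small three-subject study and evaluate head-hip technique:

```sh
transferkit simulate --out demo --seed 7 --subjects 3 --transfers 6 --minutes 9
transferkit quality --signals demo --annotations demo/annotations.csv \
    --item head_hip --classifier svm --seed 1
```

which prints (report JSON on stdout, summary on stderr):

```
classifier: svm
subject  accuracy  weighted_F1
    S01     66.7%        0.667
    S02    100.0%        1.000
    S03    100.0%        1.000
mean accuracy 88.9% (SD 19.2%)
confusion (actual x predicted, counts and row %):
                          good            not_good
        good        10 (100.0%)         0 (  0.0%)
    not_good         2 ( 25.0%)         6 ( 75.0%)
```

Each subject is scored on the folds where it was held out (accuracy and
support-weighted F1), the mean (SD) line averages subjects with one vote
each, and the global confusion matrix accumulates actual-versus-predicted
counts over all folds with row-relative percentages. Detection works the
same way on continuous recordings:

```sh
transferkit detect --signals demo --annotations demo/annotations.csv \
    --classifier all --seed 1 --out detect.json
```

The library API mirrors the CLI (`transferkit.simulate`,
`transferkit.pipelines.evaluate_quality` / `evaluate_detection`,
`transferkit.selection.cfs_select`, ...); see `docs/methods.md` for the
model details and design choices.

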