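# masgrade

Quantitative grading of elbow spasticity on the Modified Ashworth Scale
(MAS) from passive-stretch sensor recordings.

Spasticity — the velocity-dependent increase in muscle tone seen after
stroke, cerebral palsy or spinal cord injury — is graded clinically on the
six-level MAS (0, 1, 1+, 2, 3, 4) by feel: the examiner stretches the
relaxed elbow and judges the *catch*, the jerk-like instant of maximum
deceleration, and where it occurs within the range of motion (ROM).  That
judgement is subjective and rater-dependent.  `masgrade` implements an
instrumented alternative for sessions recorded with a twin-axis
goniometer (elbow angle, 1000 Hz), a handheld myometer (resisting force,
1000 Hz) and a surface EMG sensor on the biceps (2000 Hz):

1. **Preprocessing** — resultant elbow angle θ = √(θx² + θy²); 5th-order
   median and mean filters on angle and force; fix-zero levelling of the
   force; sEMG zero-mean levelling, rectification and a zero-phase
   4th-order 10 Hz Butterworth envelope, decimated onto the common
   1000 Hz timebase.
2. **Segmentation** — a session holds three slow then three fast passive
   stretches; rising phases of the elbow angle are isolated and tagged by
   protocol order.
3. **Catch detection & features** — the catch is the minimum of the
   angular acceleration inside each fast stretch; 17 features are
   computed per stretch: 8 kinematic (ROM, θ_catch, θ_catch/ROM, the
   angles at maximum sEMG and maximum force with their ROM ratios,
   ω_max), 6 kinetic (force-at-catch/initial-force, normalised force
   increment and averages, post-event force slopes) and 3 physiological
   (normalised sEMG at/after the catch and its slope).
4. **Classification** — the Logical–SVM–RF cascade:
   ROM < 10° → MAS 4 (rule); otherwise an RBF SVM (C = 15) votes and is
   trusted only for MAS 1/3; otherwise a 25-tree random forest decides
   among MAS 0/1+/2 from its masked, renormalised class probabilities.
   Both sub-models are 5-class classifiers trained on standardised,
   random-oversampled fast-stretch features with MAS 4 excluded.
5. **Evaluation** — confusion matrices, per-class precision/recall/F,
   accuracy, balanced accuracy (mean per-class recall) and
   support-weighted averages, plus a verification utility that recovers
   integer confusion counts from precision/recall values printed at two
   decimals.

Because clinical recordings are not publicly available, the package ships
a synthetic session generator (`masgrade.synthetic`) with MAS-conditioned
profiles and planted ground truth for every quantity the pipeline
estimates; the test suite asserts recovery of the planted values.

## Worked example

```sh
python examples/02_train_cascade.py
```

generates 10 synthetic sessions per grade, trains the cascade on a 90:10
stratified split and prints:

```
confusion matrix (rows = true grade, columns = predicted):
    0  1  1+  2  3  4
0   3  0   0  0  0  0
1   0  3   0  0  0  0
1+  0  0   3  0  0  0
2   0  0   0  3  0  0
3   0  0   0  0  3  0
4   0  0   0  0  0  3

accuracy 1.000, balanced accuracy 1.000
```

Each row of the matrix counts held-out fast stretches of one true grade;
a clean diagonal means every stretch was graded correctly, including the
MAS 4 stretches that the classifiers never saw (the < 10° ROM rule
catches them).  On noisy synthetic data the defaults are near-ceiling;
see `docs/methods.md` for what that does and does not imply about
clinical recordings.  `examples/01_simulate_and_extract.py` shows feature
extraction against planted ground truth, and
`examples/03_verify_published_metrics.py` re-derives published
classifier scores from their per-class rows.

A thin CLI wraps the same pipeline for shell use:

```sh
masgrade simulate --n-per-class 2 --seed 7 --out sim/
masgrade extract --in sim/ --out features.csv
masgrade train --features features.csv --seed 7 --out cascade.pkl
masgrade predict --features features.csv --model cascade.pkl --out pred.csv
```

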