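# Methods

## Signal model

Real consumer-headset EEG is replaced by a generative stand-in whose only
job is to carry controllable class-conditional spectral structure through
the exact processing chain a real recording would take.

For emotion class *k*, channel *c* and band *b* ∈ {delta, theta, alpha,
beta}, the generated signal is

    x_kc(t) = A_bg · pink_c(t) + Σ_b A_comp · g_kb[c] · n_bc(t)

where `pink_c` is unit-rms 1/f-shaped Gaussian noise (FFT-domain shaping,
DC removed), `n_bc` is unit-rms band-limited Gaussian noise (white noise
through the same 4th-order zero-phase Butterworth band-pass the analysis
side uses), `A_bg = 10` and `A_comp = 5` in microvolt-like units, and
`g_kb` are the per-class gain vectors:

| class  | boosted bands | channels | gain |
|--------|---------------|----------|------|
| calm   | alpha         | all      | 3.0  |
| happy  | beta          | frontal  | 3.0  |
| sad    | delta, theta  | frontal  | 3.0  |
| scared | theta, beta   | frontal + temporal | 2.5 |

All other gains are 1. The assignment follows the broad EEG folklore that
relaxation elevates alpha and arousal elevates beta, but the profiles are
**fixtures, not physiological claims**: their purpose is that every class
pair differs in at least one (band, channel) mean power by several
standard errors, which a property test asserts. The amplitude scale is
cosmetic (signals peak around ±50 µV); every downstream feature is either
scale-aware by design (activity) or scale-free (mobility, complexity),
and classifiers standardise features anyway.

Determinism: the seed stream is `SeedSequence(seed, spawn_key=(class,))`,
so identical `(label, duration, seed)` give bit-identical recordings and
different labels never share noise.

What the generator does *not* emulate: eye-blink/EMG artifacts, channel
cross-correlation beyond the shared band structure, non-stationarity
within a recording, inter-subject variability, and mains interference
(the modelled device notches 50/60 Hz on board). Passing tests therefore
demonstrate correctness of the pipeline and recoverability of planted
spectral structure — not expected accuracy on human EEG, where the same
pipeline would face far smaller effect sizes.

## Preprocessing

Epochs are 192 samples (1.5 s at 128 Hz), non-overlapping by default.
The length is chosen so that one epoch's flattened 14-channel content is
exactly 2688 values (the published filtered-feature length) and ten
epochs tile one 15 s decision window; both constraints are validated at
config load.

Bands are the conventional clinical edges within the 0.5–30 Hz analysis
envelope: delta 0.5–4, theta 4–8, alpha 8–13, beta 13–30 Hz (configurable
through `RunConfig.band_edges`). Filters are 4th-order Butterworth
band-passes applied forward-backward (`sosfiltfilt`, reflective padding),
giving zero phase — important because Hjorth mobility is a slope
statistic and group delay would misalign epochs. Measured behaviour:
in-band sinusoids retain ≥ 99% power, sinusoids two octaves outside a
band retain < 1%. Forward-backward application squares the magnitude
response, so re-filtering an already band-filtered broadband signal still
sheds transition-band energy (retention 0.83–0.94 depending on band);
filtering is near-idempotent only for content well inside the band.

## Features

Hjorth descriptors use population variance and unscaled first
differences, so mobility is in radians/sample; this makes values exactly
reproducible and machine-independent. Degenerate inputs: a constant
signal raises an error in single-signal calls, while batch extraction
substitutes the documented sentinel (0, 0, 0) with a warning so one flat
channel cannot abort a session. A perfectly linear signal gets mobility 0
and complexity 0 by convention. Hjorth features are computed per band
(4 bands × 3 descriptors per channel); a broadband variant is available
by passing a single-band decomposition.

The six-channel subset is AF3, F3, FC5, FC6, F4, AF4 — the montage's six
most frontal/central electrodes; the montage has no pure central (Cz-row)
sites, so fronto-central FC5/FC6 stand in. The subset is configurable.

MI ranking discretises each feature into 8 equal-frequency bins
(duplicate quantile edges merged, so constant features collapse to one
bin and MI exactly 0) and computes plug-in MI in nats with no bias
correction. The estimator is biased upward for continuous features but
the bias is shared across features of equal binning cardinality, which is
sufficient for *ranking*; ties break by ascending feature index so the
ranking is deterministic and permutation-equivariant.

## Classification

Default hyperparameters: SVM with RBF kernel, C = 1, γ = 1/n_features;
KNN with k = 5, Euclidean metric — unremarkable defaults, configurable
per call. Features are standardised inside the CV pipeline with
statistics from the training folds only (leakage-free). Cross-validation
is stratified 10-fold with seeded shuffling; the confusion matrix pools
held-out predictions, so entries sum to n and row sums equal class
counts. "Updating" a model with new sessions is retraining on the union
of stored and new epochs — the simplest semantics consistent with an
append-only epoch store; no incremental learning is attempted.

Persistence is a versioned JSON metadata file plus a joblib blob of the
fitted pipeline; version mismatch is a hard error, and a reloaded model
predicts identically to the original.

## Expressive mode

Ten consecutive epoch decisions form one window (10 × 1.5 s = 15 s,
validated in config); the feedback label is the modal class, with ties
resolved in favour of the tied label occurring latest — in a monitoring
context the subject's most recent state is the best tiebreak. Windows are
non-overlapping and aligned to the recording start; trailing partial
windows yield nothing. If the winner is sad or scared (the
negative-valence half of the class set), the feedback carries the
treatment texts stored for that emotion.

Why aggregate: if the true class wins each epoch independently with
probability p > chance, the plurality of 10 votes is correct more often
than a single epoch (at p = 0.6 over four classes, measured window
accuracy ≈ 0.93 vs 0.60 per epoch). This error-rate reduction is asserted
by simulation in the tests at exactly those conditions.

## Sessions and profiles

Training stimuli are modelled as a manifest of synthetic ids tagged with
emotion and valence/arousal quadrant signs (happy +v+a, scared −v+a,
calm +v−a, sad −v−a), 45 per class / 180 total by default; picture
content is out of scope. Display duration defaults to 3 s per stimulus
(two epochs), a typical affective-picture presentation length; it is a
free parameter of the protocol. Session recording derives one sub-seed
per stimulus from the session seed, synthesises a recording of the
display duration under the stimulus label, and labels its epochs.

Profiles are one versioned JSON file per user holding labelled epochs in
full float precision, a model reference, and an append-only treatment
history with non-decreasing timestamps.

## Problem sizes and numerical choices

The test suite and the acceptance script use 30 epochs (45 s) per class
for cross-validation, 20 recordings per class for separability checks,
500 simulated windows for the majority-vote comparison and 20 trials of
200 × 51 matrices for MI ranking — sizes at which every statistical
assertion is stable across seeds while the whole suite runs in seconds.
The acceptance script's chance floor averages five label permutations
because a single permutation's CV accuracy has standard error ≈ 0.04 and,
when feature clusters are fully separated, an expectation nearer 0.30
(the within-cluster plurality fraction of a random balanced labelling)
than the naive 0.25.

Known limitations: no artifact handling or channel-quality logic; no
overlap between decision windows; the filtered-signal feature family is
dimensionally heavy (2688) and is the weakest of the three on small
training sets; the synthetic generator's stationarity makes classification
much easier than on real EEG.
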