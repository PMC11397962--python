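# emgphasor

Phasor-based spatial synergy feature extraction for multichannel surface EMG,
with a full gait-phase-recognition evaluation harness. Channel `k` of an
`N`-channel montage is embedded at the complex direction `exp(j*k*2*pi/N)`;
the moduli of pairwise phasor differences of a per-channel base feature
(waveform length or RMS) yield a spatial-contrast descriptor `Df`, and the
generalized set concatenates `log(Df)` with `log(Df / grad_Df)`, where
`grad_Df` repeats the construction on the time-differentiated signal.

The package contains:

- `synth_emg` — synthetic labelled gait EMG: band-limited Gaussian carriers
  gated per channel by a channel-by-phase synergy gain matrix, with
  unbalanced jittered phase durations, raised-cosine envelope crossfades and
  additive sensor noise. Fully deterministic per seed.
- `preprocess` — zero-lag 4th-order Butterworth band-pass (10–400 Hz) and
  sliding-window segmentation (150 ms windows, 25 ms increment,
  majority-vote labels with later-phase tie-break).
- `features_classic` — WL, RMS, MAV, ZC, SSC and the comparator sets HTD,
  TDPSD, TDAR (Burg AR order 4), Du.
- `phasor` — the phasor embedding, `Df`, `grad_Df`, the WL-/RMS-phasor sets
  (72 columns at N=9) and their 144-column combination.
- `quality_metrics` — separability index (mean half-Mahalanobis distance to
  the most-conflicting class) and mean semi-principal axis (per-class
  geometric-mean SVD semi-axes).
- `kernel_baseline` — a minimal 84-kernel random-convolution comparator
  (Rocket-style Gaussian kernels / Mini-style two-valued patterns) pooled
  into PPV and max features.
- `evaluate` — intra-subject five-fold leave-one-trial-out evaluation with a
  pooled-diagonal-covariance LDA or an RBF SVM, reporting ACC, multiclass
  MCC (R_K), pooled confusion matrices and test-phase timing.

## CLI

```sh
# write a synthetic dataset (one CSV per trial + dataset.yaml sidecar)
emgphasor simulate --out data/ --trials 10 --cycles 2 --seed 0

# filter, window and extract one feature set
emgphasor extract --data data/ --set phasor --out phasor.csv

# feature-space quality (SI / MSA), appended to a results table
emgphasor quality --features phasor.csv --out quality.csv

# five-fold leave-one-trial-out evaluation
emgphasor train-eval --features phasor.csv --clf svm --out eval.json

# the full feature-set x classifier grid with summary tables
emgphasor benchmark --data data/ --out bench/
```

Feature sets: `htd tdpsd tdar du wlphasor rmsphasor phasor rocket
minirocket`. The trial format is generic delimited text (one column per
channel plus an integer `label` column), so externally recorded data can be
evaluated by writing it in the same layout alongside a `dataset.yaml`
(sampling rate, channel names, phase names).

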