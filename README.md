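# eegstress

Mental-stress detection from multichannel EEG, as a tested, fully
seedable pipeline. The package targets researchers and students in
biomedical signal processing who want a transparent reference
implementation of a classic metaheuristic-wrapped SVM pipeline —
every stage is a small, documented module with planted-ground-truth
tests, so it also works as a study object for adaptive filtering and
swarm optimization.

## The method

Four stages, mirroring a published stress-classification design:

1. **Eye-blink removal (NLMS).** A normalized least-mean-squares
   adaptive filter cancels ocular artifacts. With primary channel
   `d(m)`, reference tap vector `x̄(m)` (the L most recent samples of a
   0.5–8 Hz band-limited frontal blink reference) and weights `f(m)`:

   ```
   y(m) = f(m)·x̄(m),   e(m) = d(m) − y(m)
   f(m+1) = f(m) + μ e(m) x̄(m) / (‖x̄(m)‖² + ε)
   ```

   The cleaned signal is the error `e`. Adaptation is gated to
   segments where the reference tap energy is far above its median —
   i.e. to actual ocular activity (see `docs/methods.md`).

2. **Feature extraction (DCT).** A fixed, ordered bank of 24 per-file
   features over the cleaned signal and its orthonormal DCT-II
   spectrum `A(p) = α(p) Σ x(n) cos(π(2n+1)p/2N)` — moments, waveform
   statistics, and spectral descriptors including EEG band powers.

3. **Feature selection (MBPSO).** Modified binary particle swarm
   optimization: real velocities `v ← w v + c₁r₁(pbest−x) + c₂r₂(gbest−x)`
   mapped to bit-flip probabilities through the sigmoid
   `S(v) = 1/(1+e^{−v})`, scored by held-out SVM accuracy. The run
   also records the fitness extremes `f_max`, `f_min`.

4. **Classification (MWOA-tuned SVM).** A whale optimization algorithm
   searches a 3-dimensional space (kernel index, log₁₀ C, log₁₀ γ) for
   the best SVM configuration, maximizing held-out accuracy
   `(tp+tn)/(tp+tn+fp+fn)` on a per-subject 18/7 file split. In the
   *modified* variant the WOA coefficients are frozen at
   `r₁ = (f_max+f_min)/2`, `r₂ = (f_max−f_min)/2` from the selection
   stage. Decision scores are finally binned by quartiles into four
   stress levels (no / low / medium / high).

A synthetic-EEG generator (32 channels, 10–20 montage, 1000 Hz, 1/f
background, planted biphasic blinks with known windows, class-dependent
posterior band-power shifts) provides ground truth for every stage.

## Worked example

```sh
$ eegstress run-all --variant mbpso+mwoa --out run --seed 17
variant=mbpso+mwoa kernel=sigmoid accuracy=0.9286 sensitivity=0.8333 specificity=1.0000 f1=0.9000
```

This simulates 2 subjects × 25 files (4 s each), removes the planted
blinks, extracts the 24 features per file, selects 10 of them with
MBPSO (100 iterations × 20 particles), tunes the SVM kernel with MWOA,
and evaluates on the 7 held-out files per subject. The printed numbers
are the cross-subject averages of accuracy, sensitivity, specificity
and F1 on those held-out files: 0.9286 means 13 of the 14 test files
were classified correctly — the synthetic class effect (a
0.5×background beta/alpha band-power shift on posterior channels)
makes the classes nearly but not perfectly separable through the
band-power features. `run/` holds every intermediate artifact: `features.csv`,
`mask.json` (selected features plus `f_max`/`f_min`), `model.json`
(kernel, C, γ), `metrics.csv` (one row per subject plus an average
row), `predictions.csv` (per-file prediction, decision score and
stress level), and `run_report.json` with all derived seeds.

The stage verbs `simulate`, `preprocess`, `extract`, `select`,
`train`, `evaluate` expose the same flow piecewise; the library API
(`eegstress.*`) mirrors them one function per stage.

The package also ships the published per-subject benchmark table for
the 14-subject go/no-go EEG study this design comes from
(`eegstress.reference_results`); averaging its rows reproduces the
published cross-subject scores, e.g. proposed-method accuracy 0.9602.

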