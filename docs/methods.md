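# Methods

This note documents the models, the parameter choices that matter, the
synthetic data the tests rely on, and the numerical decisions taken
where the design was genuinely open.

## NLMS artifact cancellation

The canceller is a sample-by-sample FIR filter of `order` taps
(default L = 10) adapted by the normalized LMS rule with step `μ`
(default 0.5) and regularizer `ε` (default 1e-6) added to the squared
tap norm. Conservation holds by construction: cleaned + artifact
estimate reconstructs the primary channel exactly. Weights start at
zero and the first L samples are computed with zero-padded taps, not
discarded. Stability requires 0 < μ < 2; steady-state weight jitter
grows with μ (misadjustment ≈ μ/(2−μ) relative to the minimum error
power), which is why the Wiener-convergence validation experiment uses
μ = 0.005 while the pipeline default stays at 0.5, where fast blink
tracking matters more than weight precision.

**Blink reference.** The method's source design never names the
filter's reference input. We use the mean of Fp1/Fp2 (configurable)
band-limited to 0.5–8 Hz with a zero-phase 4th-order Butterworth
filter, since blinks dominate frontal low frequencies; this is
standard ocular-artifact cancellation practice.

**Gated adaptation.** A band-limited blink reference is bursty: tap
energy is 2–3 orders of magnitude above its median during a blink and
near-singular in between. Running the normalized update continuously
in the quiet stretches lets uncorrelated background drive the weights
into the classic NLMS drift/divergence regime (the near-zero tap norm
amplifies every update). The canceller therefore updates weights only
where the reference tap energy exceeds 60× its median — quiet
background peaks at ~30×, blinks at >1000×, so the gate opens only on
ocular activity. Two consequences we consider features: a blink-free
recording passes through bit-exactly (weights never move from zero),
and weight quality is set by the blink segments rather than by hours
of silence. The raw `nlms_adaptive_filter` operation keeps the
ungated textbook form; the gate lives in `remove_eye_blinks`.

## Feature bank

24 features per file, computed on one analysis signal — by default the
mean of the occipital channels (O1/O2/Oz), falling back to the mean of
all channels; which channels a per-file feature vector should come
from is underdetermined in the source design, so it is exposed as
configuration. Definitions chosen where only names were given:

- waveform length = Σ|x(i+1)−x(i)|; Wilson amplitude = #{|Δx| > 0.5·std}.
- short-time energy: mean per-frame Σx², 256-sample frames, 50% overlap.
- zero-crossing rate in crossings/second.
- SNR = 10·log₁₀ (power in the 3 largest DCT bins / remaining power).
- spectral centroid/rolloff (85%) on |A(p)|, p ≥ 1, with bin frequency
  p·rate/(2N); spectral flux = ‖|A₁|−|A₂|‖₂ between the two
  half-signal DCT spectra; band powers = mean A(p)² within the
  delta/theta/alpha/beta bands.
- cross-convolution peak = max of the convolution of two half-length,
  half-overlapping segments, normalized by total signal energy.

Degenerate inputs (zero variance, zero spectral energy) set the
affected feature to 0 with a logged warning, never an exception; batch
runs must survive a flat channel.

## MBPSO feature selection

Classical velocity update with c₁ = c₂ = 2, inertia decaying linearly
0.9 → 0.4, velocities clamped to ±6 (keeps the sigmoid out of total
saturation), positions initialized Bernoulli(0.5), velocities
U(−1,1). Defaults: 20 particles × 100 iterations. The wrapper fitness
is held-out SVM accuracy; since an empty mask cannot be scored, an
all-zero position is repaired by flipping one uniformly chosen bit.
The fitness extremes f_max/f_min are taken over every evaluation of
the run, and feed the modified whale optimizer.

The selected-subset size is not constrained by the algorithm; when a
target cardinality (default 10) is set, the final mask keeps the
dimensions most frequently selected across the final swarm, ties to
the lower index. The plain-PSO ablation replaces the sigmoid transfer
with a continuous position in [0,1] thresholded at 0.5.

## Whale optimization and the modified variant

Standard three-phase WOA: encircling (D = |C·X*−X|, X' = X*−A·D),
bubble-net spiral (X' = D·e^{bl}·cos 2πl + X*, b = 1, l ~ U(−1,1) per
update), and exploration toward a random whale when |A| ≥ 1, with
a = 2(1−t/T) and the spiral/encircle coin p ~ U(0,1). The spiral is
parameterized by l rather than the iteration counter (an exponential
in t diverges); the |A| ≥ 1 exploration trigger is the standard one —
both points the source design leaves to the WOA literature it builds
on. Positions are clamped to the search box after every move.

The modified variant freezes r₁ = (f_max+f_min)/2 and
r₂ = (f_max−f_min)/2 from the selection stage, once per run (whether
the substitution is per-run or per-iteration is unstated; per-run is
the reading that depends only on the MBPSO output). Since fitnesses
are accuracies in [0,1], both constants stay in [0,1]; A still decays
through the a-schedule, so exploration still gives way to
exploitation, but the coefficient noise is pinned. With degenerate
bounds (f_max = f_min), C = 0 throughout and the encircling step
contracts straight onto the best-known position.

## Kernel search and stress levels

The optimizer searches [0,4) × [−3,3] × [−4,1]: floor of the first
coordinate picks linear/polynomial/RBF/sigmoid, the other two are
log₁₀ C and log₁₀ γ (degree fixed at 3, coef0 at sklearn's default 0).
Features are standardized inside the fitted pipeline (training
partition only). libsvm is capped at 20 000 iterations per fit so that
pathological (C, γ) corners visited by the search stay cheap and
deterministic. The split is per-subject, file-wise, seeded: 18
training and 7 test files per subject.

Ground-truth binary stress labels are a required input: the source
experiments never define how their recordings were labeled, so the
pipeline takes labels from the user or from the synthetic generator.
The four stress levels are an interpretation: per-file signed decision
scores are binned at their 25/50/75 percentiles into
no/low/medium/high, which is monotone in the score by construction.

## Synthetic data

`generate_recording` emulates the acquisition the pipeline targets:
32 channels (10–20 labels, frontal to occipital), 1000 Hz, per-channel
1/f^slope background (slope 1.0) scaled to 10 µV RMS; eye blinks as
300 ms biphasic raised-cosine pulses (peak 100 µV frontally) at
Poisson times (12/min default), with amplitude decaying by e^(−row/2.5)
per scalp row — blinks spread broadly over frontal sites and are
negligible occipitally. The exact blink windows are returned as ground
truth. The class effect adds band-limited noise at
`class_effect`×background RMS (default 0.5) on posterior channels:
beta (13–30 Hz) for "stressed", alpha (8–13 Hz) for "calm" — the
signal the occipital band-power features detect.

`generate_labeled_dataset` is the selection/classification test bed:
informative columns N(d,1) vs N(0,1), everything else N(0,1), balanced
labels.

What the generator does *not* model: ERPs or any behavioral/task
structure, inter-channel background correlation, non-stationarity,
electrode drift or line noise. Passing tests therefore demonstrate
that each stage recovers the structure it is designed for under clean,
stationary conditions — not performance on real recordings.

## Validation experiment sizes

The validation suite (shared by the tests and the acceptance script)
uses problem sizes chosen to make each check sharp: 20 000-sample
Wiener comparison at μ = 0.005; blink removal measured on frontal-row
channels of an 8 s, 30 blinks/min recording; bit-match landscape D = 4
with 10 particles × 50 iterations over 20 seeds; informative-subset
recovery with d = 1.5 and 120 samples/class — strong enough that the
informative triple tops the exhaustive C(10,3) ranking, weak enough
that accuracy has not saturated into ties; sphere function with 20
whales × 100 iterations; XOR kernel selection with clusters at (±1,±1)
and σ = 0.25, where an exhaustive grid shows RBF strictly dominant
(poly/sigmoid with coef0 = 0 are odd under x → −x and cannot represent
the even XOR boundary). End-to-end runs use 2 subjects × 25 short
files with reduced swarm sizes; stage seeds derive from one global
seed by a fixed affine scheme so ablation variants see identical data
and splits.

## Known limitations

- The per-subject benchmark table ships for the worked example and the
  averaging check; the pipeline does not attempt to reproduce its
  per-subject values, which depend on external recordings and on
  labels their source never defines.
- The four-level stress mapping is relative to each run's score
  distribution; it is not calibrated across runs or subjects.
- The heuristic labeler for real recordings (frontal beta power above
  the subject median) is a demo convenience, not part of the
  benchmarked method.
- Feature extraction collapses each file to one analysis signal; there
  is no per-epoch or time-resolved feature support.
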