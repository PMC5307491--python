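# Methods

This note documents the models implemented in `emgtrace`, the choices made
where the design was genuinely open, and what results on the synthetic
benchmark do and do not show.

## The decoding problem

A subject traces one-stroke shapes on a tablet while 8 sEMG channels are
recorded at 1 kHz: 7 decoding channels over forearm and upper-arm muscles
(d1=ECRB, d2=ED, d3=ECU, d4=FCR, d5=TB, d6=BB, d7=DM) and one trigger
channel over Adductor Pollicis. Pen coordinates arrive every 50 ms. The
decoder regresses the coordinate *differences* (Δx, Δy) per 50 ms window
on the per-window RMS of the 7 channels, then reconstructs the trace by
cumulative summation from the true stroke start point. Working on
differences keeps the mapping causal, bounds the target range, and ties
the targets to the dynamics of muscle activation rather than to absolute
pen position.

## Feature extraction

- Windows are adjacent and disjoint, 50 ms (50 samples), starting exactly
  at the detected onset; a trailing partial window is discarded (the
  truncation rule is a package choice; nothing downstream depends on it).
- Onset detection takes the first trigger sample with |v| ≥ 40 μV and
  returns the index of the maximum |v| within the following 20 ms. The
  threshold is applied to absolute amplitude (polarity handling was open),
  the 20-sample peak window includes the crossing sample, and ties break
  to the earliest index.
- An optional zero-phase 4th-order Butterworth band-pass (10–500 Hz) plus
  a Q=30 notch at 50 Hz is provided for raw signals. The contract is the
  attenuation profile (≥ 20 dB at 50 Hz, ≤ 3 dB at 100 Hz), not the filter
  family; with a 1 kHz sampling rate the upper band edge is clipped just
  below Nyquist. Whether RMS should be taken from raw or filtered signals
  was open; the pipeline extracts from the (optionally) filtered signal,
  and the synthetic generator's signals are already band-limited, so the
  default pipeline skips the filter.

## The GEP engine

Chromosomes are 6 genes of head 15 and tail t = h(n_max − 1) + 1 = 16
(gene size 31), linked by addition. The function set is
{+, −, ×, ÷, Sqrt, Exp, Inv, x², Sin, Cos}; terminals are d1..d7. Fitness
is f = 1000/(RMSE + 1). The printed form of the error equation omits the
square and root, but names the quantity Root Mean Square Error; standard
RMSE = √(mean(squared error)) is implemented.

Numerical choices:

- **Protected arithmetic** (the engine's finiteness contract): x÷0 → 1,
  Inv(0) → 1, Sqrt(x) = √|x|, Exp's argument capped at ±700, sin/cos
  arguments clipped to ±1e15, every intermediate clamped to ±1e300 with
  NaN (indeterminate forms like 0·∞) mapped to 0. Any chromosome therefore
  evaluates to a finite number on finite inputs.
- **Selection**: roulette wheel on raw fitness with single-individual
  elitism (the best is copied unmodified), making best-so-far fitness
  non-decreasing. All-zero fitness falls back to uniform sampling.
- **Operator order** per generation: replication → mutation → inversion →
  IS → RIS → gene transposition → one-point → two-point → gene
  recombination. Inversion/transposition segment lengths are drawn
  uniformly from {1, 2, 3}. IS never inserts at the root; RIS requires a
  function in the head and is skipped otherwise.
- **Rates**: the defaults are the published training settings (population
  200, 2000 generations, mutation 0.0014 per symbol, inversion and the
  transpositions 0.0055, recombinations 0.0028). These are tuned for a
  200 × 2000 budget. `GepConfig.scaled_down()` is the small-budget preset
  used by the benchmark: population 100, ~2 point mutations per chromosome
  (rate 2/186), inversion/transposition 0.1, one-/two-point recombination
  0.3, gene recombination 0.1 — the classic GEP textbook values — plus a
  stagnation patience. The preset was fixed from those canonical values,
  not tuned on benchmark outcomes.
- **Termination**: generation cap or reaching max fitness; `patience`
  (stop after N generations without improvement) and `target_fitness` are
  exposed for budgeted runs.
- **Random numerical constants (RNC)**: the published best formulas
  contain constants, yet the stated gene size 31 = h + t leaves no room
  for a constant domain, so whether RNC was used originally is unclear.
  The engine implements RNC as an option (per-gene Dc of length t,
  constants uniform in a configurable range, `?` terminals resolved in
  karva reading order, Dc point mutation and constant refresh at the
  mutation rate), default **off**. Recombination crosses symbol strings
  while each child keeps its own Dc/constant arrays — a documented
  simplification.
- Two independent models F(x), F(y) are evolved separately; there is no
  multi-output chromosome. One seeded generator drives all stochastic
  steps, so a fixed seed reproduces the run bit-for-bit.
- Gene phenotype values are memoised by ORF during a run; this is a pure
  optimisation and does not affect results.

## The published reference formulas

The two published best within-group models are shipped as fixed expression
trees evaluated under the same protected arithmetic. The published
typography collapses fraction bars and exponents; the transcription table
below records the reading used (terms not listed are read literally, with
juxtaposition as multiplication):

| printed fragment | reading used | note |
|---|---|---|
| `d5d4` (F(x), first sin) | d5/d4 | fraction; gives the d5/d4 term whose d4=0 case the protection rule covers |
| `d7exp((exp(cos(d1+d4+42.63)d7))2)` | d7 / exp((exp(cos(d1+d4+42.63)·d7))²) | outer: fraction; inner `cos(...)d7`: **flag** `x_inner_d7`, default multiply |
| `d2sin(d3+8.89−d5)d7−d4` | d2·sin(d3+8.89−d5)/(d7−d4) | fraction |
| `(d2−3.53)262.73` | (d2−3.53)²/62.73 | collapsed exponent + fraction |
| `2d1−0.45+1d3` | 2·d1 − 0.45 + 1/d3 | 1/d3 as a fraction |
| `12.21d2` (F(y)) | 12.21/d2 | **flag** `y_12_21_d2`, default divide (the multiplicative reading saturates exp for physiological RMS) |
| `0.78d5d3` (F(y)) | 0.78·d5·d3 | product |

Both flagged alternates are implemented
(`printed_model("x", x_inner_d7="divide")`, etc.). Under the default
reading F(x) references all 7 terminals and F(y) exactly 6 (d4 absent),
matching the published statements. No numerical fidelity to the original
study is claimed — the original RMS inputs are unavailable.

## The Kalman baseline

State s_i = (Δx_i, Δy_i); order-1 MVAR transition s_i = A s_{i−1} + v_i,
Q = Cov(v); measurement s_i = H z_i + w_i with z_i the 7 RMS values,
R = Cov(w). The source text types w_i as 7×1, but the measurement equation
forces w_i ∈ ℝ² and R 2×2; the dimensionally consistent form is
implemented. A and H are fitted by OLS without intercept on pooled
training windows (lag pairs never straddle trial boundaries); Q and R are
residual sample covariances. The filter is the three-step recursion with
gain K = P_pred (P_pred + R)^{−1} — the observation matrix is the identity
because the "measurement" handed to the filter is the regression
prediction H z_i. Initialisation (unstated in the source): ŝ_0 = training
mean delta, P_0 = Q. P is re-symmetrised each update. Higher AR order is
not implemented; a ridge term for (P + R) inversion is exposed for
degenerate covariances.

## The synthetic generator

No public recordings exist for this task, so the generator plants the
statistical structure the decoder assumes and the experiment design around
it (12 one-stroke shapes × 40 repetitions = 480 trials per synthetic
subject, randomized order, deterministic per seed).

- **Shapes**: four lines, arch/inverted arch (half-ellipses),
  circle/ellipse, plus the four reversed lines (same point set, reverse
  traversal). Coordinates are tablet units, y-down; size 400 units stands
  in for the 12 × 12 cm template; default stroke duration 1.5 s
  (31 coordinate samples).
- **Trial-to-trial variability**: iid jitter of 1% of shape size per
  sample, plus a smooth low-frequency drift with sd 10% of shape size.
  The drift emulates human motor variability — without it a line's
  cross-axis coordinate would be jitter-only and its per-trial CC²
  meaningless, whereas human data show large cross-axis variance on
  exactly those shapes. Chosen once as a generator design decision.
- **Forward model**: channel m has unit preferred direction p_m and gain
  g_m (μV per tablet-unit/window); its window envelope is
  baseline + g_m·max(0, p_m·(Δx, Δy)) — rectified cosine tuning. The
  default seven directions are 0°, 180°, 90°, 270°, 45°, 135°, 225° with
  unit gains, baseline 8 μV, additive sensor noise 2 μV; envelopes stay
  well inside the 0–2000 μV sensor range. Opposite-direction pairs at
  equal gain make d1 − d2 ∝ Δx and d3 − d4 ∝ Δy exactly, so the planted
  mapping lies inside the GEP function set (planted-formula recovery is a
  fair test) and inside the Kalman measurement model's span.
- **Carrier**: each channel's signal is the envelope modulating band-limited
  (10–450 Hz) Gaussian noise whose per-window RMS is normalised to 1, so
  with zero sensor noise the window RMS equals the envelope exactly.
- **Trigger**: rest noise sd 3 μV (far below the 40 μV threshold), a
  100 ms burst from movement onset whose first sample is the 200 μV peak —
  modelling the sharp stylus-button click — so threshold-crossing onset
  detection recovers the true onset index exactly and features align 1:1
  with coordinate differences.

What the generator does **not** model: muscle synergies and co-contraction,
electrode shift, fatigue, impedance drift, cross-talk, or any
physiologically calibrated EMG-to-kinematics relation. Passing benchmarks
on it demonstrates that the pipeline is implemented correctly and can
recover a recoverable mapping; it does not certify accuracy on real
muscles.

## Evaluation

CC² = 1 − Σ(ŝ−s)²/Σ(s−s̄)², per coordinate, computed within each trial
and then averaged across trials (never pooled residuals); values may be
negative and are reported as-is; a constant actual series raises and the
trial is flagged. Reconstruction always starts from the true stroke start.
The 70/30 split is stratified by shape (plain random splitting could leave
a shape without test trials); within-group pools all shapes into one model
pair, between-group fits one pair per shape. Multi-subject aggregation is
emulated by independent synthetic subjects (different seeds) averaged the
same way. No significance testing between methods is performed.

## Benchmark problem sizes

The full benchmark (`scripts/acceptance.py`) uses the complete 480-trial
session: within-group GEP with population 100, ≤ 200 generations,
best-of-5 restarts, fitness cases capped at 2000 by seeded subsampling;
between-group with best-of-2 restarts, ≤ 150 generations per shape and
coordinate; the Kalman baseline uses all training windows. The test suite
runs the same pipelines at 12 repetitions per shape with fewer restarts.
These sizes are the package's standard configurations; both clear the
accuracy marks with large margins because the planted mapping is, by
construction, at least as learnable as a real recording session.

## Known limitations

- The forward model is a stand-in; absolute benchmark accuracies say
  nothing about real sEMG performance.
- Overlapping analysis windows, frequency-domain/wavelet features,
  velocity/acceleration state augmentation, RTS smoothing and EKF/UKF
  variants are out of scope.
- GEP search is stochastic; small budgets occasionally converge to local
  optima (mitigated by restarts, never eliminated).
- The published formulas are evaluated as transcribed; residual typography
  ambiguity is confined to the two documented flags.
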