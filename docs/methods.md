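# Methods

`nldbench` is an offline benchmark of linear and nonlinear decoders for
2-degree-of-freedom finger velocity decoding from intracortical
spiking-band power (SBP). Because it runs on synthetic sessions with a
known ground-truth encoding, every stage — feature extraction, dataset
preparation, decoder training, and evaluation — is testable end to end.
This note records the models, the parameters that matter, and the design
choices made where the design was genuinely open.

## Task and kinematics simulator

The simulated task is a random-target acquisition task for two finger
groups, index (IDX) and middle-ring-small (MRS). Positions live on the
"flex" axis, the fraction of the movement range from full extension (0)
to full flexion (1); velocities are in flex·s⁻¹. Per trial:

- a target center is drawn uniformly per DOF such that the target (width
  15% of the movement range by default) fits inside [0, 1];
- the hand pauses at its current posture for a reaction time drawn
  uniformly from 150–350 ms;
- a minimum-jerk reach of duration uniform in 400–900 ms moves each DOF to
  its target;
- the hand holds inside the target for the hold time (750 ms default, the
  task's training-mode hold) with Gaussian positional jitter of SD 0.004
  flex per 50 ms bin (also applied during the reaction pause, so velocity
  is never exactly zero for long runs — real flex-sensor traces always
  micro-move).

Everything is generated directly on the 50 ms bin grid; velocity is
defined as the backward difference of position, so the discrete-derivative
invariant holds exactly. The resulting velocity distribution is peaked at
zero with heavy tails (excess kurtosis > 0; more than half of all bins
below 10% of peak speed), the qualitative signature of fast reaches
embedded in long holds that separates linear from nonlinear decoders.

Failed trials (optional, rate 0 by default) stall just outside the target
until the 10 s timeout. The trimming protocol removes them before any
analysis, so the default generator emulates a session of successful
behavior; the failure path exists to exercise the trimming rule.

"Middle 600" trimming uses a centered window with `floor((n-600)/2)`
leading trials dropped. For online-style block filtering the first 5
trials are always excluded and "middle 100" is computed on the original
block with the leading drop forced to be at least 5.

## Encoding model

Channel `c` has expected SBP

    E[sbp_c | kin] = b_c + g_c · link(w_c · x),    x = [v, p, |v|] ∈ R⁶

with baseline `b_c ~ U(8, 25)` (arbitrary SBP units), gain
`g_c ~ U(8, 20)`, and tuning weights drawn per channel (velocity SD 2.5,
position SD 0.35, speed SD 0.3 for the saturating link). Observed SBP
adds Gaussian noise (SD = 0.35 × baseline) and clamps at zero, matching
the nonnegativity of rectified band power.

Three link functions are available:

- **linear** — the identity; the kinematics → SBP map is affine (velocity
  weight SD reduced to 0.9 and baselines inflated above the worst-case
  modulation so the map is nonnegative without clipping). This is the
  control condition under which ridge regression is the right model class.
- **saturating** (default) — a logistic `1/(1+e^{-u})`. A doubly
  saturating link was chosen deliberately: a softplus-style link is
  asymptotically affine, and averaging ~96 such channels leaves an affine
  decoder near-optimal. The logistic compresses the high-velocity tails of
  single-channel activity, which is precisely the regime where affine
  decoders under-predict speed — the behavior the benchmark is designed to
  expose.
- **quadratic** — `u + 0.25u²`, a milder nonlinearity kept for
  sensitivity analyses.

Context shifts (spring load, wrist rotation, both) perturb only the
encoder: the velocity-weight pair of every channel is rotated in tuning
space (0.5, 0.8, and 1.2 rad for spring / wrist / spring-wrist), the gain
is scaled (×1.25, ×0.85, ×1.35) and the baseline offset (+2, −1.5, +3
units). "normal" is the identity, and a global `shift_magnitude` scales
all three components (0 gives identical encoders in every context — the
null control). Kinematics are untouched by construction, emulating task
manipulations that modulate neural activity while behavior stays similar.

What the generator does **not** emulate: spike-sorted units, electrode
noise nonstationarity, within-session learning by the subject, or any
feedback coupling between decoding errors and subsequent behavior (the
sessions are open-loop). Passing directional tests on this generator shows
that the pipeline detects the intended effects when they are present; it
is not evidence about effect sizes in real recordings.

## SBP feature chain

Raw 30 ksps broadband is polyphase-decimated to 2 ksps, bandpassed
300–1000 Hz with a 4th-order Butterworth applied forward-backward (zero
phase; the upper edge sits at Nyquist of the intermediate rate and is
nudged just inside for a well-posed design), rectified, and averaged into
non-overlapping 50 ms bins. Synthetic sessions are generated directly in
binned form (`prebinned` flag in the container metadata); the chain exists
for raw containers and is validated against analytic oracles (rectified
sine mean 2/π, stopband attenuation, positive homogeneity).

Decoders consume windows of the current bin plus 2 lookback bins (150 ms).
The first 2 bins of a session yield no window rather than zero-padded
history; an explicit index array records the alignment to kinematics rows.

## Decoders

**Ridge regression (RR).** Closed form on standardized (z-scored) flattened
windows, λ = 0.001, bias unpenalized — so the λ → ∞ limit collapses to the
target means. Standardization constants are stored in the model; λ is
scale-sensitive, so they are part of the contract.

**Dual-state (DS).** Two ridge regressions fit on high- and low-speed bins
(pooled-speed median split by default), blended by an LDA state
classifier fit on the same windows. The published description of this
decoder family fixes the goal of the adaptive threshold — maintain a 1:1
fast/slow classification ratio over a sliding window — but not the
controller. Here:
the threshold θ ∈ [0, 1] shifts the LDA posterior,
`p_fast = clip(p + 0.5 − θ, 0, 1)` (identity at θ = 0.5); a bin is
classified fast when `p > θ`; and θ integrates the error between the
100-bin sliding-window fast fraction and the 0.5 target with an additive
step of 0.01 per bin. On stationary streams the long-run fast fraction
settles within ±0.05 of target.

**TCN.** A temporally-convolved feedforward network: a bank of 16 filters,
each a kernel over exactly the 3 history bins, applied to every channel
independently (weights shared across channels, never mixing channels at
the conv stage), then two fully connected ReLU layers of 256 with batch
normalization and dropout 0.5, and a 2-unit linear output. Ablations:
onlyBN (no dropout), onlyDP (no batchnorm), noBNDP (neither). Training
minimizes MSE with Adam (lr 1e-4, weight decay 1e-2, L2 coupled into the
gradient), 10 epochs for TCN/onlyBN and 80 for the no-batchnorm variants,
on targets z-scored per DOF; a per-DOF single-weight/single-bias
regression maps normalized predictions back to flex/s. Batch size is 32:
with the learning rate and epoch budget fixed by protocol, the batch size
controls the number of optimizer steps, and 512-sized batches demonstrably
cannot reach convergence in 10 epochs on 400-trial sessions (normalized
training loss stalls above the variance of the target). Layer widths,
filter count, and dropout rate are configurable; the defaults train in
tens of seconds on one CPU core.

**LSTM.** Single layer, hidden size 300, trained on within-trial sequences
of 20 bins (shorter sequences are front-padded with the trial's first bin;
sequences never cross trial boundaries). Inputs and targets are
normalized; two noise injections augment training — a per-sample,
per-channel bias (SD 0.1) and white noise per element (SD 0.2). Loss is
the MSE of the final sequence output. Adam lr 2e-4, weight decay 0.003,
with a plateau scheduler (patience 800 iterations, factor 0.5, at most 2
reductions). Ten epochs (~4000 iterations on a 400-trial session) by
default.

**ReFIT recalibration.** Intention estimation relabels recorded decode
velocities per DOF: outside the target, an away-from-center velocity has
its sign flipped (magnitude preserved); inside the target the velocity is
set to zero (the convention of the intention-estimation literature);
toward-target velocities pass through. The base TCN is then fine-tuned on
the relabeled data for exactly 500 iterations at lr 2e-4, all other
hyperparameters inherited.

**Velocity redistribution.** For closed-loop-style training sets, training
rows are importance-resampled (with replacement, size preserved) toward a
triangular speed density on [0, max speed] with peak at half the maximum
— flattening the overwhelming preponderance of low-speed bins. The
triangular target is the package's reading of an otherwise undefined
protocol step and is exposed as a strategy interface.

The neural-network core (dense / batchnorm / dropout / channel-wise
temporal convolution / LSTM, Adam) is implemented in numpy with
hand-written gradients, runs in float32, and is verified against central
finite differences to ~1e-6 relative error per layer and for the full
LSTM backward pass. Weight decay follows the classic Adam convention
(decay added to the gradient before the moment updates). All randomness —
initialization, batch shuffling, dropout masks, noise injection — flows
through explicit per-instance generators, so identically-seeded trainings
are bit-identical.

Trained models serialize to single-file artifacts — ridge to JSON, network
decoders to an HDF5 checkpoint holding the architecture config, weights
(including batchnorm running statistics), normalization constants, output
rescaler, loss trace, and provenance — and round-trip to bit-identical
predictions.

## Dataset preparation

Per session: failures removed, middle 600 trials kept, final 100 (original
order) held out, remaining 500 shuffled once and split into five 100-trial
blocks; fold i validates on block i and trains on the other four (~400
trials). Shuffling is always at the trial level; bins within a trial stay
contiguous so feature windows never mix trials. The geometry generalizes
to five blocks of k (k = 50 is used for the smaller-session ablation
protocol below).

Multi-context sessions prepare each context independently, then build per
fold: a **full** set (all four 400-trial training sets, 1600 trials) and a
**mixed** set (25% of each context's already-shuffled training set,
sampled sequentially — the first quarter of the first context, the second
quarter of the second, and so on — 400 trials total, 100 per context).

## Metrics

- **MSE** over all bins and both DOFs; instance groups reported as
  mean ± SE.
- **Speed regimes**: per-DOF speeds pooled over (bins × DOFs); the high /
  low regimes are strictly above / below the 90th / 10th
  linear-interpolation percentile. Constant-speed input yields empty
  masks (documented degenerate case); empty-mask statistics are reported
  as missing.
- **Velocity PMFs / KL divergence**: histograms over pooled velocities on
  100 equal-width bins spanning the reference (hand-control) range,
  shared by all compared PMFs, out-of-range values clipped to the end
  bins. KL(p‖q) in nats with q floored at 1e-9 and renormalized, so
  divergences of empirical histograms are finite; p-zero bins contribute
  nothing.
- **Median prediction deviation**: per (time, DOF) the sample SD (ddof 1
  — instances are a sample of possible trainings) across
  identically-trained instances, then the median over all (time, DOF)
  entries.
- **Trial metrics**: in-target is the closed interval center ± width/2 on
  both DOFs. Time-to-target is the first simultaneous in-target bin;
  orbiting time runs from first acquisition to the start of the terminal
  in-target run that completes the hold; orbiting rate is the fraction of
  trials with nonzero OT. Mean TT excludes zero-TT trials; mean OT uses
  nonzero OTs. Fitts throughput sums log2(1 + D/W) over DOFs (D =
  start-to-center distance, W = target width) divided by acquisition time.

## Statistics

Paired and two-sample t-tests (pooled-variance Student by default, Welch
by flag), one- or two-tailed, alpha 0.01; zero-variance paired differences
report p = 0 or 1 by sign with a degeneracy flag rather than dividing by
zero. Two-proportion z-test with pooled proportion. The nested two-way
ANOVA decomposes SS into day, run-within-day, and residual (F against the
residual mean square); a crossed variant with a day × run interaction is
also available because "interaction" is undefined in a purely nested
design — both outputs are emitted and the crossed decomposition is
cross-checked against statsmodels in the test suite. No multiple-testing
correction by default. Type-I error of every test is calibrated under
pure-noise nulls to [0.005, 0.02] at nominal 0.01 over 10⁴ replicates.

## Experiment problem sizes

The packaged experiments run on one CPU core in minutes; sizes were chosen
as the smallest at which the directional effects are stable across seeds:

- **Decoder comparison**: five seeded 96-channel, 600-trial saturating
  sessions; one instance of RR / TCN / LSTM per session trained on one
  400-trial fold, evaluated on the 100-trial holdout.
- **Regularization ablation**: one 48-channel session under the 300-trial
  protocol (250 kept / 50 holdout, five 50-trial blocks), 20 instances per
  variant, all on a 10-epoch budget so training-speed comparisons read off
  the same trace length.
- **Context generalization**: one four-context session (600 trials per
  context), ridge decoders on all six training sources × five folds,
  tested on every single-context holdout. Ridge is used here because the
  context effect is a property of the data preparation, not of decoder
  capacity, and it makes the experiment deterministic given the session.

## Known limitations

- The encoding model is memoryless given the current bin's kinematics;
  real SBP has temporal dynamics beyond what position/velocity/speed carry.
- Closed-loop behavior is out of scope: trial metrics (TT, OT, OR,
  throughput) are computed on simulated or replayed trajectories.
- The dual-state adaptive-threshold controller and the triangular
  redistribution target are this package's own concrete choices for
  under-specified protocol steps; both are flagged at their definition
  sites and exposed as configuration.
- The LSTM's noise-injection granularity (per sample rather than per
  batch) follows the more common augmentation reading of the protocol.
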