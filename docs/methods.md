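# Methods

## Problem setting

Emotion classification from eye movements treats a trial as a feature
vector `X ∈ R^D` (fixation, saccade, blink and pupil statistics) with a
class label in `{0, …, C−1}`. The features split naturally into two
*views* — gaze dynamics (fixations, saccades) and pupillometry — that are
driven by the same underlying affective state but corrupted by different
noise sources, most prominently per-individual offsets. The package trains
a dual-branch network on the two views jointly, with an auxiliary loss
that pulls the views' learned representations toward a shared direction.

## Architecture

Each view passes through its own branch:

1. **Convolutional stack.** Two same-padded 1-D convolutions
   (`in → 64 → 128` channels, kernel 3, ReLU). Feature-table input is
   treated as a single-timestep sequence with `D` channels; raw sequences
   keep their temporal axis. Same padding preserves the timestep count.
2. **Multi-scale temporal context.** Average pooling at kernel sizes
   8–512 (clamped to the sequence length), each pooled map upsampled back
   by nearest-neighbour repetition and averaged with the unpooled map.
   The whole step is a fixed row-stochastic linear operator on the time
   axis, so it is exactly the identity on time-constant maps and on
   single-timestep input. A `concat` mode (concatenate pooled maps,
   project back with a 1×1 convolution) is available in the config.
3. **Transformer encoder.** Sinusoidal positional encoding
   (`PE(pos,2i)=sin(pos/10000^{2i/d})`, `PE(pos,2i+1)=cos(·)`) added once
   before two encoder blocks: 8-head self-attention and a feedforward
   sublayer, each with residual connection and layer normalisation,
   dropout 0.3 inside both sublayers.
4. **IFFN.** The feedforward sublayer is the incremental feature
   feedforward network: a partial convolution over the leading
   `ceil(0.25·C)` channels (the rest pass through untouched; an optional
   validity mask renormalises by the count of valid samples under the
   kernel), a square linear map `W1` with GELU, a channel split into
   halves `(u1, u2)`, elementwise gating `r = u1 ⊗ DepthwiseConv(u2)`,
   and a final square map `W2` with GELU. Channel-halving would make the
   gated product 64-wide against the 128×128 `W2`; the default restores
   full width by concatenating the gate branch (`concat(r, u2)`), and a
   config flag switches to a rectangular 64→128 `W2` instead. An optional
   linear encode–decode bottleneck (`d → d/2 → d`) in front of the IFFN is
   off by default. A width-matched plain two-layer FFN is available as the
   ablation baseline.
5. **Heads.** Per-view encoder outputs are mean-pooled over time. The
   classifier takes the concatenation of both pooled views through a
   linear map and softmax. Separately, per-view projection networks
   (`128 → 64 → 128 → o`, ReLU, `o = 32` by default) produce the
   representations the alignment loss operates on. `o = 32` balances
   head capacity against the cost of the objective; the oracle comparisons
   use `o = 1` where a single canonical pair is the ground truth.

## Cosine-similarity alignment objective

With projected views `H1, H2` (samples as rows) centred per dimension,

    J = tr(H1ᶜᵀ H2ᶜ) / (‖H1ᶜ‖_F ‖H2ᶜ‖_F) ∈ [−1, 1],

the cosine of the two matrices flattened to vectors. J is invariant to
positive rescaling of either view and requires no distributional
assumptions. The per-sample mean cosine `1/n Σ cos(h1⁽ⁱ⁾, h2⁽ⁱ⁾)` is an
alternative reading of the same idea and is exposed as a config option;
the trace form is canonical because its gradient and the joint loss are
defined in terms of it. Note the robustness profiles differ: the
per-sample mean bounds any single sample's influence by 2/n regardless of
magnitude (each sample enters only through its direction), while the
trace form's Frobenius norms let a very large row dominate. The
comparative robustness test in the suite therefore exercises the
per-sample form against a per-dimension Pearson objective.

The exact gradient is

    ∂J/∂H1ᶜ = H2ᶜ/(‖H1ᶜ‖‖H2ᶜ‖) − J·H1ᶜ/‖H1ᶜ‖²,

symmetrically for `H2ᶜ`. A truncated form that keeps only the first term
(`as_printed`) is also provided for comparison; the two coincide exactly
when J = 0 and the truncated form is non-zero even at the maximum J = 1,
where the true gradient vanishes. Training uses the exact gradient
(through automatic differentiation); finite-difference checks cover both.

The training loss negates the objective, `L_align = −J`, so minimising the
total loss maximises alignment. Norms inside the training-mode loss carry
an ε = 1e−12 guard; library entry points are strict and raise on zero
norms. The linear-CCA oracle (whitened cross-covariance SVD, ridge 1e−8 on
covariance diagonals) provides the closed-form target that linear
projection networks trained on J must approach.

## Joint loss and optimisation

    L = ω1 · L_CE + ω2 · L_align,   ω1 + ω2 = 1,

with `L_CE` the mean categorical cross-entropy. Defaults ω1 = 0.1,
ω2 = 0.9 compensate the roughly tenfold scale difference between the two
terms. The alignment term is computed per minibatch on that batch's
projections (centering within batch), standard practice for stochastic
CCA-style training. Optimisation is Adam (β = (0.9, 0.999), learning rate
5e−4, batch 128) with decoupled weight decay 0.01; the learning rate is
multiplied by 0.1 once at epoch ⌈epochs/2⌉ (the decay factor is given as a
single number, so a one-step schedule is the simplest faithful reading;
it is config-overridable). Features are imputed by the training-split
median and z-scored with training-split statistics. The capacity sanity
check (single-batch overfit to training accuracy 1.0) runs with ω1 = 1,
since it probes the classification path alone.

The network is implemented on a compact reverse-mode autodiff core written
in numpy (`ictd.autodiff`); every primitive's gradient is verified against
central finite differences in the test suite.

## Evaluation protocol

Cross-validation partitions *subjects*, never trials: subjects are
shuffled with the run seed and split into k groups; each fold tests one
group (20% of subjects at k = 5) and trains on the rest, so no individual
contributes to both sides. Metrics: multiclass accuracy
(trace of the confusion matrix over its total — the multiclass
generalisation of (TP+TN)/(TP+FN+TN+FP)), macro-averaged F1 (the averaging
convention is stated because "F1" alone is ambiguous), the row-normalised
confusion matrix, and a 95% CI on accuracy from the normal approximation
`mean ± 1.96·sd/√k` over fold accuracies (reported per fold, labelled as
across-fold spread). Independent from-scratch recomputations of the
confusion matrix and F1 back the library implementations in the tests.

The ablation harness retrains under identical fold assignments and seeds
with: the IFFN swapped for the plain FFN; ω2 forced to 0 (pure
cross-entropy — the alignment value is still logged each step but sits
outside the gradient path); and both. Reports carry a fold-assignment
hash so comparability is checkable.

## Synthetic data generator

`generate_dual_modality` draws trial i of class c, subject s as

    x_v = A_v (μ_c + z_i) + o_{s,v} + ε_{i,v}     for view v ∈ {gaze, pupil}

with class means `μ_c` on a regular simplex of edge `class_separation`
(separability is controlled exactly), `z ~ N(0, I)` a shared latent,
fixed seeded loading matrices `A_v`, per-subject offsets `o_{s,v}` drawn
*independently per view* (sd `subject_shift_sd`), and iid noise ε. Labels
cycle over classes (balanced to within one trial); subjects own
contiguous trial blocks. Defaults: 4 classes, 10 subjects × 200 trials,
latent dim 8, view dims (16, 6), separation 8, noise sd 0.5, subject sd
0.5. With `latent_dim=1`, unit loadings and noise sd σ, the two views are
noisy copies of one latent and their correlation has the closed form
1/(1+σ²) — the closure test between generator, sample correlation and CCA
oracle.

Because the subject offsets are view-specific while class signal and
latent are shared, the alignment loss has a mechanism to earn its keep:
it discourages representation directions that are not mirrored in the
other view, i.e. exactly the subject-offset directions that break
cross-subject generalisation. The ablation-direction comparison therefore
uses a high-individual-variability condition (20 subjects × 50 trials,
separation 4, noise sd 1, subject sd 5). What the generator does not
emulate: realistic oculomotor dynamics, non-Gaussian feature marginals,
label noise, and view-specific *informative* structure; passing tests
show internal consistency of the method under its own assumptions, not
performance on real recordings.

`generate_gaze_stream` realises fixation/saccade/blink plans as uniformly
sampled recordings: fixations scatter around their centre (sd
`dispersion`), saccades are constant-velocity linear ramps between
consecutive centres, blinks flag validity false. Intervals are half-open
`[onset, offset)` and a sample belongs to the interval containing its
timestamp, so a 500 ms fixation at 100 Hz yields exactly 50 samples. The
planned intervals are the detector's ground truth. When choosing plan
dispersions note the implied apparent velocity `d·√2·f` against the
detector threshold.

## Event detection and features

The detector is I-VT: point-to-point velocity above a threshold (default
30 position-units/s) marks saccadic samples, below marks fixational;
segments shorter than minimum durations (60 ms fixation, 10 ms saccade)
merge into their neighbour; invalid runs become blinks, and events of the
same kind separated only by a blink are merged back (a blink inside a
fixation does not terminate it). The threshold and minima are exposed
because no single setting suits all units and sample rates.

Preprocessing linearly interpolates invalid gaps up to 75 ms and applies a
centred moving average (width 3) within each valid run — edge windows
shrink, so linear ramps are preserved away from edges.

Feature conventions: population moments (ddof = 0); CV = sd/mean, missing
when the mean is 0; Fisher (excess) kurtosis and adjusted Fisher–Pearson
skewness, switchable to raw moments; fixation dispersion is the per-axis
coordinate range, summed over axes for "total dispersion"; frequencies
are events per second of recording; "saccade latency" is the mean gap
between consecutive saccade onsets (a documented choice — the term has no
universal definition); pupil diameter is the left/right mean per sample
in the distributional dialect, per-eye in the statistics dialect. Missing
features (absent event kinds) are NaN and imputed by the training-split
median at modelling time. ANOVA screening keeps features whose one-way F
across labels has p < 0.05; constant features have undefined F and are
dropped with the reason recorded.

The discrete-emotion → circumplex mapping used for the five-emotion
protocol: anger/disgust → (high arousal, negative valence), sadness →
(low, negative), tenderness → (low, positive), neutral → (medium, medium).

## Problem sizes and numerical choices

The test suite and the acceptance script run everything on synthetic data
at sizes chosen to keep a single-CPU run comfortable: n = 2000 trials for
classification recovery (30 epochs), n = 10000 for the correlation
closure, 500 gradient-ascent steps for the oracle comparison, 5 seeds ×
25 epochs at n = 1000 for the ablation direction, 50 random plans for the
detector. Softmax and cross-entropy are max-shifted; the objective's
norms carry the ε guard in training mode only; convolution kernels longer
than a sequence are sliced to their centred sub-kernel, which is
mathematically identical under zero same-padding.

## Known limitations

- The conclusions the synthetic benchmarks support are about internal
  consistency, not about real eye-tracking data; no real dataset ships
  with the package (readers for the public datasets' proprietary
  containers are out of scope — export to CSV first).
- On this package's synthetic benchmarks the alignment term does not
  improve subject-independent accuracy: with the default dropout the two
  views' projections are perturbed by independent dropout noise and J
  stays near 0 throughout training, so the 0.9-weighted term mostly
  injects gradient noise; with dropout disabled J converges toward 1 but
  the generator's shared latent carries all within-class variation, so
  alignment amplifies no class-specific signal and accuracy falls. The
  benefit reported on real recordings evidently rests on cross-view
  structure this generator does not emulate; the ablation-direction test
  documents the measured ordering rather than assuming it.
- Sequence-mode (T > 1) paths are exercised by tests at small sizes; the
  pure-numpy implementation is not tuned for long sequences.
- The transformer is encoder-only; no decoder or cross-view attention.
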