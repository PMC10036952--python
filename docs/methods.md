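# Methods

## The problem

Bistable kinetic-depth-effect (KDE) displays — rotating dot spheres whose
rotation direction is ambiguous — exhibit *perceptual memory*: presented
intermittently with long blanks, they tend to reappear in their previously
dominant state. `percmem` implements a reverse-correlation analysis of how
brief random disambiguation sequences embedded in a *prime* display alter
(a) the perception of the prime itself and (b) the memory read out by the
following fully ambiguous *probe*, together with the hierarchical Bayesian
models used to quantify the recovered sequences. Because the pipeline is
driven by a synthetic observer with a known ground-truth kernel, every
stage is testable end to end without human data.

## Stimulus model

A disambiguation segment biases rotation by making front-surface dots
larger than back-surface dots. Strength `m ∈ [0, 1]` maps linearly between
the two anchor states: fully ambiguous (0.2/0.2 dva) and maximal contrast
(0.4/0.0 dva), i.e. front = 0.2(1+m), back = 0.2(1−m). Only the anchors are
physically fixed; the linear interpolation is the simplest map consistent
with both and the analysis never depends on its exact shape.

Per-segment strengths are drawn i.i.d. uniformly from the 21-level grid
{−1.0, −0.9, …, 1.0} and stored internally as integer tenths so the grid
survives serialization exactly. Three schedules are built in: 10 × 30 ms
segments covering the first 300 ms of an 800 ms presentation
(`onset_only`), the same 10 segments filling a 300 ms presentation
(`full`), and 20 segments split between the first and last 300 ms of a
1000 ms presentation (`onset_offset`).

Sign convention: raw sequences use an absolute code (positive cues
rightward rotation). For analysis they are re-signed relative to the
leading probe's report, so positive means "toward the currently dominant
state". This alignment is an involution and is applied once, at triplet
construction.

## Synthetic observer

The observer is a state machine over reports, not a cognitive model. Its
memory state is the last probe's reported direction. A prime's aligned
sequence `s` is pooled linearly through a temporal sensitivity kernel κ
into a drive `d = Σ κ_k s_k`, and

    P(same as previous probe) = λ/2 + (1−λ) · logistic(θ + g·d)

governs both the prime percept (gain `g_p`, baseline `θ_p`) and the next
probe percept (the memory channel: `g_m`, `θ_m`). Lapses are symmetric
(λ/2 to each direction) so no direction bias leaks into the analysis.
Misses occur with probability `p_miss`; after a missed response the next
trial is always a probe, as in the experimental procedure.

Defaults (units: drive is strength-weighted kernel sum, dimensionless):

| parameter | default | why |
|---|---|---|
| κ | 0.6·exp(−(k−2)²/4) for k ≤ 5, else 0 | early-onset sensitivity, peak at the 2nd 30 ms segment, silent after 150 ms |
| θ_p = θ_m | 4.0 | strong persistence at zero drive (≈ 98% same) |
| g_p | 12.0 | puts the observer in the high-gain regime (see below) |
| g_m | 24.0 | memory flips twice as easily as perception |
| λ | 0.02 | occasional stimulus-independent errors |
| p_miss | 0.02 | occasional missed responses |

Two choices deserve comment.

*Kernel sign.* κ is stored as a **positive** sensitivity profile: it
weights evidence *for* the cued direction. Because switches are caused by
evidence against the current state, the expected reverse-correlation image
of switch trials is the **negated** kernel (`switch_template`): a moderate
negative disambiguation peaking at the second segment and fading to fully
ambiguous. Recovery tests therefore correlate the estimated image with the
template, not with κ itself.

*Gain regime.* The classification-image amplitude is non-monotone in gain:
in the noise-dominated (low-gain) regime it grows with `g`, while in the
high-gain regime the effective switch threshold `−θ/g` moves toward zero
as `g` grows, so the trials that switch carry *gentler* cues. Only the
high-gain regime reproduces the target phenomenon — a channel that flips
more easily shows a weaker image. A parameter scan placed θ = 4, g_p = 12
comfortably inside that regime (switch rates ≈ 29%/39%, memory/perception
amplitude ratio ≈ 0.87); these values were fixed before any acceptance
measurement and are not revisited.

## Triplets and reverse correlation

Trials are grouped into probe–prime–probe triplets (sliding by default:
a probe serves as trailing probe of one triplet and leading probe of the
next; a disjoint mode is available since the original design is ambiguous
on this point). A triplet requires valid reports on all three trials; a
missed prime invalidates only its own triplet. Outcomes form a 2×2 against
the leading probe's report: prime changed / memory changed, giving the four
classes {both, prime-only, memory-only, none}. Selection sets union the
relevant classes: *prime-changed* = {both, prime-only}, *memory-changed* =
{both, memory-only}.

The reverse-correlation estimate is the per-segment arithmetic mean of
aligned sequences over a selection. Intervals are 97% percentile bootstrap
(2,000 iterations), resampled separately per segment. Group intervals use
the two-stage scheme: resample within participant, average per
participant, then average the participant means (unweighted). Percentile
rather than BCa intervals are used throughout. Empty selections raise an
explicit error rather than returning silent zeros.

## Models

All models describe the selected trials' per-segment strength
(`bias`, one observation per selected trial × segment) as Gaussian around
a structured mean. Because the mean depends on data only through the
(participant, segment, condition) cell, fits use exact sufficient
statistics — cell counts, cell means, pooled within-cell sum of squares —
making the likelihood cost independent of trial count. Pointwise
log-likelihoods for LOO are reconstructed per observation afterwards.

**Hierarchical linear**: `μ_i = α_{P_i} + β_{P_i}(Int_i − 1)` with
correlated random intercepts/slopes: `(α_P, β_P) ~ MVNormal((α, β), S)`,
`S = diag(σ_α, σ_β) R diag(σ_α, σ_β)`, priors `α, β ~ Normal(0,1)`,
`σ_α, σ_β, σ ~ Exponential(1)`, `R ~ LKJ(2)`, implemented noncentered via
the Cholesky factor of `R`. The `Int − 1` centering makes the intercept
the first segment's mean.

**Hierarchical additive**: `μ_i = (B·w_spline)_{Int_i} · w_{P_i}` with a
clamped cubic B-spline basis `B` (six functions, evenly spaced interior
knots over segment index 1..N; segment index, not onset time, is the
covariate so that both models share an axis). Priors:
`w_spline ~ Normal(0,1)`, `log w_P ~ Normal(0, σ_P)` (noncentered),
`σ_P ~ Exponential(10)`, `σ ~ Exponential(1)`. The strong prior on σ_P
keeps participant weights near 1 so the sign and magnitude of the spline
weights remain interpretable; weights are strictly positive by
construction.

**Dual-condition additive**: every parameter is duplicated per condition
(perception vs memory) except the spline weights, which are *independent*,
*correlated* — pairs `(w_j^a, w_j^b)` bivariate normal with a common
correlation ρ ~ LKJ(2), noncentered — or *identical*. ρ measures the
similarity of the two curves; per-participant, per-condition scaling
weights carry amplitude differences, which is what makes the
identical-weights model the natural vehicle for the "memory needs gentler
cues" contrast.

## Inference

Posteriors are sampled with an affine-invariant ensemble sampler over the
unconstrained parameterization (log scales, tanh correlations, noncentered
random effects), using differential-evolution moves, which traverse the
soft amplitude ridge of the multiplicative hierarchy far better than the
stretch move. Walkers (64 by default) are treated as chains for
rank-normalized split-R̂ and ESS; a ConvergenceWarning fires if any R̂
exceeds 1.01. Default chain lengths (40k steps thinned by 80; 60k for the
dual models and 100k for the linear model, whose random-effect correlation
mixes slowest) were sized so R̂ ≤ 1.01 holds on recovery simulations.
Initialization is a small Gaussian ball around a least-squares projection
of the pooled cell means (spline weights) or zeros (everything else).

Model comparison uses PSIS-smoothed leave-one-out ELPD with standard
errors from pointwise values; ΔELPD is reported against the best model
with the SE of the paired pointwise difference, and relative weights are
the pseudo-BMA softmax `exp(elpd_k − max)/Σ exp(elpd_j − max)`, which sum
to one. Interval summaries are 97% equal-tailed percentile intervals plus
97% HPDIs (narrowest contiguous window of sorted draws); HPDIs are the
right summary for skewed quantities such as ρ and are never wider than the
percentile interval on the same draws.

## What the synthetic data does and does not show

The generator reproduces the statistical structure the analysis relies on:
alternating probe/prime sessions with miss handling, uniform grid
sequences, logistic report rules with a shared early-onset kernel and a
more sensitive memory channel. It deliberately omits neural persistence
and adaptation dynamics across blank durations, reaction times, eye
movements, observer-specific long-term biases and any nonlinearity in
evidence pooling. Passing tests therefore demonstrate that the *pipeline*
recovers what this class of observer encodes — not that human perceptual
memory works this way, and not the human study's posterior numbers, which
depend on the original raw data.

## Numerical choices and degenerate inputs

- Strengths on the exact integer-tenths grid; off-grid inputs are
  rejected at parse time with the offending line number.
- Unconstrained sampler coordinates are hard-bounded at |x| < 15, which
  also caps runaway residual scales on degenerate all-zero data.
- Quantiles use linear interpolation (NumPy default); the HPDI window is
  ⌈mass·n⌉ sorted draws.
- LOO subsamples draws (stride, ≤ 1000 by default) to bound the
  draws × observations matrix.
- Ties in the HPDI window argmin resolve to the leftmost window.
- Group bootstrap requires ≥ 2 participants; random-effect models require
  ≥ 2 participants and ≥ 2 segment levels.

## Problem sizes

Recovery and acceptance checks run at 4 synthetic participants with
10,000 primes each for reverse-correlation recovery, 2,000 primes each for
the dual-condition scaling contrast, 40 replicates per cell for
model-selection recovery, 500 replications of n = 200 for bootstrap
calibration, and 10⁶ draws for the interval oracle — sizes at which each
property is comfortably powered on a single CPU.

## Known limitations

- The ensemble sampler needs long chains on these ridged posteriors;
  gradient-based samplers would be more efficient per effective draw.
- The exact knot vector and any basis normalization of the original
  six-spline construction are unpublished; the clamped even-knot basis
  here matches the published boundary behavior (edge functions peak at the
  edges) and partition of unity, but is not guaranteed identical.
- Relative model weights use the softmax reading of "weights that add up
  to 1"; stacking weights are a reasonable alternative and would change
  numbers, not conclusions, in the tested scenarios.
- With only six weight pairs, ρ in the correlated variant is weakly
  identified; its posterior leans on the LKJ(2) prior unless the two
  curves are tightly constrained.
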