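# Methods

## Model and identification

A trial `Y ∈ R^{m×τ}` is treated as the output of a first-order linear
Gaussian state-space system: `x(t+1) = A x(t) + B v(t)`,
`y(t) = C x(t) + ω(t) + ȳ`, with `A ∈ R^{n×n}` carrying the temporal
dynamics and `C ∈ R^{m×n}` (orthonormal columns) the spatial appearance.
Identification is the closed-form subspace method: SVD of the trial gives
`C` (leading left singular vectors) and the state trajectory
`X = Σ Vᵀ`; the transition matrix is the one-step least squares
`A = X₂ X₁†`.  Maximum-likelihood / EM estimation is deliberately out of
scope — the closed form is the method, chosen for cost and determinism.
Noise covariances `Q, R` are reported only as empirical residual
covariances on request; the fit never uses them.

**Mean handling.**  By default the per-channel temporal mean is removed
before the SVD (`demean=True`), the robust choice for signals with DC
offsets.  This estimator is, however, *not* exact on noise-free data: a
finite trajectory of a strictly stable system can never have a zero
sample mean (`Σ_t A^t = (I − A^τ)(I − A)^{-1}` is nonsingular for
spectral radius < 1), so centering perturbs the state recursion by an
O(1/τ) constant and leaves a small bias in `A` (Martin d² ≈ 1e-4 at
τ = 200; a unit test verifies the bias falls as τ grows).  With
`demean=False` the SVD factors `Y` directly; on data whose channel means
are zero — AC-coupled or band-passed recordings, and the noise-free
synthetic trials — this raw path identifies the generator *exactly* (to
machine precision), and the closed-form correctness checks use it.

**Conventions.**  SVD column signs are fixed (largest-magnitude entry of
each column of `C` positive) so fits are bit-reproducible.  Pseudoinverses
use a relative cutoff of 1e-10·σ_max because `X₁` can be rank-deficient
on short epochs.  Rank-deficient trials raise a degenerate-input error by
default; an opt-in flag truncates `n` to the effective rank instead.
Default state dimension is `n = 16` (where motor-imagery accuracy peaks
in practice); every experiment here that uses the 4-dimensional synthetic
generator passes `n = 4` explicitly.  The default observability order is
`L = n`.

## Distances

The squared Martin distance `D² = −2 Σ log cos θᵢ` is computed from the
principal angles between the column spaces of the two order-`L`
observability matrices.  Two independent routes exist: singular values of
`Uaᵀ Ub` for orthonormal bases (the production path), and the constrained
generalized eigenproblem on the Gram blocks `OaᵀOa, ObᵀOb, OaᵀOb` (the
cross-check oracle); tests require agreement to 1e-8.  Cosines are clipped
at ε = 1e-12 so near-orthogonal subspaces yield a large finite distance
rather than +∞ (engaged clips are flagged in the diagnostics); a computed
d² below 1e-12 is snapped to exactly zero so self-distances are exact.
Models with different state dimensions are an error unless the caller
opts into zero-padding.  Stability of `A` is not required since only
finite orders are stacked.  Descriptor matrices (denoised observability
matrices) are compared either by the same subspace distance on their
column spaces — the default, since the descriptor *is* a Grassmannian
point and rank may drop during denoising — or by plain Frobenius
distance; a Mahalanobis-style variant whitens flattened descriptors by a
ridge-regularized covariance estimated on the training set (ridge 1e-6).

## Low-rank + sparse decompositions

All solvers are inexact ALM: alternate the proximal maps (singular-value
thresholding for the nuclear term, entrywise soft thresholding for the ℓ1
term), then one dual ascent step with geometric penalty growth.  Defaults:
`α = 1/√max(shape)` (the standard robust-PCA weight), `β = 1.0`,
`μ₀ = 1.25/σ_max(X)`, `ρ = 1.5`, `tol = 1e-7` (relative constraint
residual), `max_iter = 500`; the dual is initialized as `λ₀ = X/J(X)`
with `J(X) = max(σ_max(X), α⁻¹‖X‖_F)`.  Hitting the iteration cap
returns `converged=False`, never an exception.  The aggressive `ρ = 1.5`
schedule converges quickly to a *feasible* point that is slightly
suboptimal for the convex objective; the high-accuracy cross-check
against a Douglas–Rachford solve of the same program therefore runs the
solver at `ρ = 1.005, tol = 1e-12`, where the two agree to ~1e-10.  A
partial-SVD (Lanczos) fast path is opt-in; the reference path uses full
SVDs for bit-stable results.

**Three-way split.**  `X = A + B + E` with the channel-common penalty
`β Σ_{i≠j} ‖Bᵢ − Bⱼ‖²` read over *ordered* pairs (the unordered reading
only rescales β).  The B-subproblem has the closed form
`Bᵢ = (μMᵢ + 4β Σⱼ Mⱼ)/(μ + 4βm)`, which preserves column sums and is
verified against a quasi-Newton minimizer.  Sweep order is A, E, B.
`β = 0` is rejected: the subproblem then degenerates to `B = M` and
annihilates the other parts.  The A-vs-B split is not identifiable when
the common part is itself low-rank (a row-constant matrix has rank ≤ 1),
so only reconstruction, B-row similarity and E-sparsity are contractual.
At the default α the exact optimum genuinely places a modest fraction of
clean signal mass in E (ℓ1 vs nuclear economics on small entries); with a
larger sparse weight (α ≈ 0.5) a noise-free fixture yields `E = 0`
exactly.  Raw time-domain signals are a poor substrate for low-rank
structure, so the `lr+csp` pipeline decomposes band-pass-filtered epochs
(8–30 Hz) per trial by default; a trial-stacked mode and a spectral
representation are possible through the same API.

**Descriptor denoising.**  `O = D + E` by robust PCA of the observability
matrix.  One caveat discovered during development and honored by the
tests: `O` is `Lm×n` with rank equal to its column count, so *any* matrix
of that shape is "low-rank", and entrywise spikes injected directly into
`O` are not identifiable — no α both preserves clean structure and strips
such spikes.  The operation's default weight is therefore
`α = 1/√min(shape)` (pricing the sparse term by the thin dimension;
the generic `1/√max` misreads most of the decaying block rows as
outliers), and its value lies in shaving noise-dominated singular
directions of descriptors fitted from *corrupted epochs*, which is what
the end-to-end benchmark measures.

## Baselines

CSP solves the generalized eigenproblem `(S₁, S₁+S₂)` on class-averaged,
per-trial trace-normalized covariances and keeps `p = 3` filter pairs
from the spectrum ends; features are `log(varⱼ/Σ varⱼ)` of the filtered
trials.  Trace normalization makes exact channel-scale invariance only
approximate (eigenvalues move at ~1e-2 under a 10× channel rescale) while
leaving end-to-end predictions unchanged.  CSSP augments each trial with
a τ-delayed copy (channels doubled, overlap window kept); the delay is
chosen by 5-fold cross-validation on the training split over 1–10 samples
unless fixed.  LDA is the pooled-covariance Fisher discriminant with
equal priors (midpoint threshold), shrinkage-regularized with a warning
when the pooled covariance is singular; binary CSP+LDA extends to
multiclass by one-vs-rest with a max-margin vote, while the KNN route is
natively multiclass.  The Butterworth band-pass (8–30 Hz, order 4) is
applied forward-backward (zero phase).  A 21-electrode motor-cortex
montage constant is provided and applied only when channel names match.
Independent-component artifact removal is an upstream cleaning step
outside this package; the pipelines accept pre-cleaned input.

## Classification

Distance-based KNN with `k = 1` by default (the nearest-neighbor rule;
`k` is exposed).  Neighbors are ordered by (distance, label), so exact
distance ties break toward the smaller label — this makes predictions
invariant to training-set order; a voting tie shrinks the neighbor set
one item at a time until it resolves.  Non-finite distances exclude the
corresponding training item.  The evaluation harness requires an explicit
disjoint train/test split (overlap is an error, never silently handled)
and fits everything — filters, delays, decompositions, classifiers — on
the training split only.

## Synthetic generator

Each class is a block-rotation transition matrix (damped oscillators at
chosen frequencies and spectral radii; a zero frequency gives a real
pole) with a random orthonormal measurement matrix, driven by Gaussian
state noise with a 50-sample burn-in for stationarity.  The benchmark
conditions are two classes at 8 channels × 200 samples (100 Hz), sharing
pole frequencies of 10 and 22 Hz (one in each sensorimotor band) and
differing in damping — spectral radius 0.6 (sluggish) vs 0.95
(sustained) — with observation noise calibrated per trial to 10 dB SNR.
Optional components: a channel-common 1 Hz sinusoidal "resting" waveform
(the simplest signal whose rows are mutually similar, emulating shared
background); and sparse artifacts — exactly `⌊fraction·m·τ⌋` entries per
trial at ±amplitude, with an option to scale the amplitude relative to
the clean-signal standard deviation (the artifact benchmark uses 2% of
entries at 5× signal scale).  Everything is bit-reproducible from the
config seed.

What the generator does *not* emulate: 1/f background spectra, volume
conduction with realistic leadfields, non-stationarity across trials,
eye/muscle artifact morphology, or inter-subject variability.  Passing
tests therefore demonstrate the correctness of the algorithms and the
internal consistency of the pipeline under the stated state-space
assumptions — not expected accuracy on recorded EEG.

## Problem sizes

The test suite and the acceptance script run at deliberately small sizes
chosen to exercise every code path while keeping runs reproducible on a
single CPU: 50 random systems for the exactness check, 40×40 rank-2
robust-PCA instances over 10 seeds, 100 model pairs for the
distance-oracle comparison, and 10-seed benchmarks of 60 trials each
(30/class, stratified 2:1 holdout).

## Known limitations

* The closed form identifies only the observable, excited part of the
  state; heavily damped modes in short windows can fall below numerical
  rank and trigger the degenerate-input contract.
* The Martin distance compares finite-order subspaces; two systems
  agreeing on the first `L` Markov blocks are indistinguishable at order
  `L`.
* The three-way split's A/B attribution is non-identifiable by
  construction (see above); downstream use should rely on `A + B` or on
  the descriptor route.
* EDF import covers EDF/EDF+ with annotation-based cues; proprietary
  competition formats are left to external converters.
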