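# Methods

## Data model

A movie is a real matrix `A` of `m` timepoints by `n` pixels, each frame
flattened row-major over `(y, x)` (2D) or `(z, y, x)` (3D); pixel indices
are 0-based. All analysis runs on the *centered* movie: each pixel's
temporal mean is subtracted, which makes the right singular vectors of `A`
the principal components of the pixel covariance. Centering is per pixel,
not per frame; per-frame centering would leave pixel offsets in place and
change every error figure downstream.

Neighbourhoods are Moore neighbourhoods (8-connected in 2D, 26-connected in
3D) truncated at the image border. No padding is used: padded borders would
inject artificial covariation exactly where the estimator is supposed to
report its absence.

## Sampling probabilities

Three strategies produce a probability vector over pixels:

* **uniform** — baseline, `p_j = 1/n`.
* **norm** — `p_j = |A_:j|²/‖A‖²_Fr`. This is the distribution under which
  the Monte-Carlo approximate-SVD guarantees hold.
* **covariation** — `p_j = |L_:j|²/‖L‖²_Fr` with
  `|L_:j|² = Σ_r (A_:j·A_:r)²` over the neighbours `r` of `j`. Implemented
  by shifting the frame stack along each neighbour offset and accumulating
  squared temporal inner products: O(mn) per offset, never materialising
  the `n × n` local covariance. `‖L‖_Fr` falls out of the same pass.

A movie whose local covariation vanishes identically (possible, e.g., for
exactly neighbour-orthogonal columns) has no covariation distribution; the
code raises rather than silently falling back to another strategy.

## Sampling procedures

*With replacement* draws `c` independent columns and rescales each by
`1/√(c·p_j)`, making `CCᵀ` an unbiased estimator of `AAᵀ`. *Without
replacement* performs `c` sequential draws, renormalising the probabilities
over the not-yet-selected pixels at every step — implemented literally as
that loop (O(nc)) rather than via order-statistics shortcuts, because the
sequential procedure is the contract and `c` is small in practice.
Zero-probability pixels are never drawn.

The *covariation energy* of a sample is `Σ |L_:j|²/‖L‖²_Fr` over its
**unique** indices. Adaptive sampling draws without replacement under
covariation probabilities until the running energy reaches a threshold
(default of interest: 0.95); if every positive-probability pixel is
exhausted first, the full set is returned.

One `numpy.random.Generator` seeded by the caller governs each sampling
call, so repetition studies are exactly reproducible.

## NIPALS PCA

Components are extracted sequentially. Each component initialises its score
vector from the residual column of maximal norm (lowest index on ties) and
iterates `s = Cᵀt/(tᵀt)`, `t = Cs/(sᵀs)` until the relative Euclidean
change of `t` falls below `tol` (default 1e-9, `max_iter` 500), then
deflates `C ← C − t sᵀ`. Deflation subtracts an exact projection, so score
columns are pairwise orthogonal to machine precision regardless of `tol`.
Components are sign-canonicalised so each loading vector's
largest-magnitude entry is positive. If the residual vanishes before `k`
components (rank deficiency) the decomposition returns fewer columns and a
warning flag rather than noise components.

The exact baseline runs the same NIPALS on the full matrix. The approximate
variant runs it on the sampled `C` only and obtains full-size images via
the Moore–Penrose pseudoinverse, `S = T⁺A`; the exact path uses the same
`S = T⁺A` formula for uniformity (for a full NIPALS basis this coincides
with the loadings up to normalisation). The default rank is `k = 30` —
20–30 components suffice to capture glomerular structure in this kind of
movie; lower components mostly explain noise.

## Error bounds

For norm sampling with replacement, with `H_k` an orthonormal basis of the
sample's top-k left subspace:

* deterministic, every run:
  `‖A − H_k H_kᵀ A‖²_Fr ≤ ‖A − A_k‖²_Fr + 2√k ‖AAᵀ − CCᵀ‖_Fr`;
* in expectation at `c ≥ ⌈4k/ε²⌉`:
  `E ‖A − H_k H_kᵀ A‖²_Fr ≤ ‖A − A_k‖²_Fr + ε‖A‖²_Fr`.

`verify_bounds` evaluates both sides per run: `H_k` is the QR
orthonormalisation of the NIPALS scores of `C` (orthogonal by deflation but
not unit norm); the optimal `‖A − A_k‖²` baseline comes from the SVD
singular-value tail, deliberately independent of the NIPALS implementation
being exercised. Both sides are reported, not just a verdict, because the
bound is loose — on the synthetic reference conditions the measured left
side sits at roughly 60% of the right side — and the slack is the
scientifically interesting part. When `c < k` (huge ε) the sample spans
fewer than `k` directions; `H` simply has fewer columns, the bound's `k` is
unchanged. Default repetitions: 30, for a stable mean in the expectation
check.

## ICA

fastICA (scikit-learn's symmetric/parallel estimator, log-cosh contrast,
tol 1e-6, max_iter 1000, random orthogonal initial unmixing derived from
the seed) runs on the whitened rows of `S` (spatial mode) or columns of `T`
(temporal mode). The estimator centers its input internally, which would
perturb the rank-k reconstruction; the module therefore applies the learned
square unmixing matrix `W` to the *uncentered* PCA factors —
`S_ica = W S`, `T_ica = T W⁻¹` (spatial) or `T_ica = T Wᵀ`,
`S_ica = (Wᵀ)⁻¹ S` (temporal) — so `T_ica S_ica = T S` holds exactly and
estimated sources carry only an irrelevant constant offset. ICA order and
sign are arbitrary; components are returned by decreasing non-Gaussianity
(excess log-cosh contrast) and compared via greedy absolute-correlation
matching. Candidate glomerulus positions are extracted from component
images by thresholding `|coefficient|` at a quantile (default 0.99).

## Synthetic movies

The generator emulates the structure of antennal-lobe recordings, not their
optics:

* **geometry** — default 64 × 64 pixels, a desk-scale stand-in for real
  recordings of 20k–150k pixels; 6 concatenated measurements × 40 frames.
* **glomeruli** — isotropic Gaussian profiles (σ = radius/2) truncated at
  the radius, default radius 5 px; default centres are non-overlapping
  (overlap is allowed but flagged).
* **responses** — per measurement, a transient with onset frame 10, a
  3-frame saturating rise, then `(1+u)e^{−d/4} − u e^{−d/12}` decay with
  undershoot fraction `u = 0.35`, two pulses 10 frames apart (mirroring
  double odor pulses). Amplitude units are arbitrary fluorescence units.
  Default amplitude patterns are sparse odor codes — each glomerulus
  responds strongly (≈ 2.0) to essentially one odor with weak side
  responses — so planted timecourses are near-orthogonal, as the ICA model
  assumes of genuine sources.
* **bleaching** — an additive exponential decay (amplitude 0.1, time
  constant 20 frames) restarting at every measurement and shared
  identically by all pixels. This is a deliberate simplification: in real
  recordings bleaching scales with local dye concentration and so is itself
  spatially structured. The shared-trend form makes it a clean rank-1
  artifact for ICA to remove, but it also spreads trend covariation over
  the entire background, which is why its default amplitude is a residual
  (≈ 5% of peak response) rather than raw-fluorescence scale.
* **noise** — i.i.d. Gaussian per pixel and frame, default sd 0.15 (peak
  SNR ≈ 13 at a glomerulus centre). Independence makes neighbourhood
  covariation a pure signal criterion; real shot noise and optical blur
  both violate this in the direction of *more* background covariation.

Under these defaults the covariation distribution places ≥ 0.9 of its mass
on the (1-pixel-dilated) glomerulus supports, sampled-PCA error decreases
monotonically with the sample fraction towards the exact error, and the
15%-sample pipeline recovers every planted source. Passing tests
demonstrate these properties *for this noise model*; they do not establish
robustness to correlated noise, movement, or structured bleaching, which
real data exhibit (movement correction is assumed done upstream and is out
of scope).

## Numerical choices and degenerate inputs

* Probabilities are validated to sum to 1 within 1e-12 and be nonnegative.
* Sequential without-replacement draws guard the cumulative-sum boundary
  so zero-probability pixels are never selected through rounding.
* `argmax` tie-breaks (NIPALS initial column) resolve to the lowest index.
* All-zero movies, zero local covariation, `c` exceeding the
  positive-probability support, and rank-deficient samples raise or flag
  explicitly; nothing falls back silently.
* Wall-clock runtimes are recorded in evaluation tables but never asserted.

## Problem sizes

The test and acceptance workloads run at deliberately desk-scale sizes
chosen as the package's reference conditions: the 64 × 64 reference movie
(240 × 4096), a 100 × 1,000 movie for the bound checks (k = 5, ε = 0.5,
c = 80, 30 repetitions), and ≤ 8 × 8 grids where an O(n²) oracle
materialises the full local covariance matrix.
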