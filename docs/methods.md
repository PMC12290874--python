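# Methods

This note records the model, the estimation machinery, the synthetic study
conditions, and the numerical choices made where the design was open. It
states no empirical number that the test suite or `scripts/acceptance.py`
does not itself compute.

## Model

Activity on an `N`-region structural graph with weights `C` (nonnegative,
symmetric, zero diagonal) and distances `D` (mm) is modeled in the
frequency domain. Finite conduction speed `v` (m/s) delays each connection
by `τ_ij = d_ij/v` (distances are converted mm → m so `v` stays in
physical units), producing the complex Laplacian `ℒ(ω) = I − α C*(ω)`
with `c*_ij = c_ij e^{−jωτ_ij}`. The long-range neural response is the
Fourier transform `F_g(ω) = 1/(1+jωτ_g)²` of the gamma kernel
`f(t) = (t/τ_g²) e^{−t/τ_g}`.

Under driving input that is white across regions and time, the model
cross-spectral density is the harmonic superposition
`F̂(ω) = Σ_k |γ_k(ω)|² u_k u_k^H` with
`γ_k = 1/(jω + τ_g^{-1} λ_k F_g)`. Band FC sums `F̂` over 10 equally
spaced frequencies per band (endpoints included — the endpoint convention
is a package choice), normalizes by the diagonal, takes the element-wise
modulus, and zeroes the diagonal. Diagonal normalization cancels the input
variance and every local (mesoscopic) transfer term, which is why only
`(τ_g, v, α)` remain.

**Validity of the closed form.** The harmonic sum equals the true
covariance of `X = UΓU^H P` only where the eigenbasis is orthonormal
(`U^H U = I`). That holds exactly at ω = 0 and to good approximation while
delay phases `ω d/v` are small; at alpha-band frequencies on a
16-region graph with ~70 mm distances, `‖U^H U − I‖∞` reaches ~0.2–0.5 and
the closed form deviates from the propagated covariance by a comparable
relative amount. The Monte-Carlo validation (20,000 draws, 3-standard-error
criterion) is therefore run in the small-delay regime — a 4-region graph
at the delta-band centre — where the derivation's assumption is accurate;
the zero-frequency matrix-inverse check is exact. This is an honest
limitation of the harmonic description, not of the implementation.

## Preprocessing

Raw tract weights are capped at the 0.99 quantile of the nonzero entries
(tractography weights are heavy-tailed; the quantile threshold is a
package default, exposed in the API), interhemispheric homolog pairs are
floored (default 1% of the cap value) to restore callosal connections that
tractography under-counts, and the matrix is sqrt-degree normalized
(`w_ij/√(deg_i deg_j)`), so `ℒ(0)` is the standard normalized Laplacian
shifted by the coupling term. Preprocessing is idempotent by contract: the
returned connectome carries a `preprocessed` flag and a second call is the
identity (literal re-application of capping plus degree scaling is not a
mathematical fixed point, so the flag is the meaningful reading).

## Empirical coherence

Band coherence from `N × T` recordings: zero-phase 4th-order Butterworth
band-pass (SOS), split into 100 equal non-overlapping epochs (trailing
remainder dropped), DPSS multitaper spectra (time-bandwidth 4, 7 tapers),
cross-spectra accumulated **across epochs and tapers**, magnitude
coherence per frequency bin, averaged over in-band bins. Accumulating
before normalizing is what the standard connectivity toolboxes do; a
per-epoch coherence averaged afterwards would carry an `O(1/√K)` bias that
never vanishes with more epochs. Entries are clipped to [0, 1], the
matrix symmetrized, diagonal zeroed.

The multitaper estimate is a biased, range-compressed estimator of the
model's band-sum coherence: correlations between the two on
model-generated data are high (the acceptance script computes ~0.9 at
600 s) but parameter estimates obtained *through* the coherence channel
carry a systematic distortion, most visible on `v`. The end-to-end
integration test therefore uses a 50% per-coordinate recovery tolerance,
versus 25% when fitting model-generated FC directly.

## Inference

Parameters are mapped to an unconstrained space coordinate-wise with
`s = logit((θ−lo)/(hi−lo))`; posteriors over θ use the exact Jacobian
correction (sum of per-coordinate log-derivatives), which makes every
posterior sample respect the bounds by construction and every marginal
integrate to one over its admissible interval.

The prior is `N(ŝ_ANN, I)` with `ŝ_ANN` a dual-annealing point fit
(default 200 iterations, L-BFGS-B local refinement capped at 25 iterations
per restart) of the loss `1 − Lin(minmax model FC, minmax observed FC)`.
Lin's concordance is used as the fitting loss throughout, for the
annealing, the Wilson–Cowan evolutionary fit, and the eigen-mapping fit
alike.

Sequential posterior estimation runs three rounds (default) of M = 1000
simulations: draw `s` from the proposal, compute band FC (stacked across
bands for the band-shared variant), add Gaussian entry noise exactly as
the observation model does — mirrored across the upper triangle, clipped
to [0, 1], zero diagonal (`noise_sd` default 1.0, mirroring a
standard-normal noise convention on FC entries; recovery experiments use
0.05, and the conditioning observation is never noise-augmented). The
training simulator must match the observation model in every detail:
an earlier variant that added unclipped, unsymmetrized noise to the
simulations shifted their minmax features systematically relative to the
clipped observation and biased the conditional mean by tens of percent.

The conditional density family is Gaussian: features are per-band
minmax-scaled upper-triangle vectors, embedded by a 30-component PCA, and
an MLP (two hidden layers of 50 tanh units, L-BFGS, weight decay 1e-2)
learns the conditional mean; least squares at fixed covariance is the
Gaussian maximum-likelihood objective, so each round maximizes the same
mean log-density criterion as flow-based neural posterior estimation
within this family. Weight decay replaces held-out early stopping (not
applicable to a full-batch L-BFGS fit). The conditional mean at the
observation is the coordinate-wise median over the full-data network and
the five cross-validation fold networks — bagging that suppresses an
occasional wild fold prediction.

Two covariances are computed from the residuals: the in-sample covariance
drives the proposal schedule (tight, so later rounds concentrate
simulations near the conditional mean), while the *reported* posterior
covariance comes from 5-fold cross-validated residuals, which honestly
reflect the regressor's predictive error. The conditioned density is used
directly as the next round's proposal, with no analytic Gaussian
importance correction: that correction is exact only when `q` is the true
proposal-posterior, and with a regression-based `q` whose covariance
reflects estimator error it subtracts two nearly equal precisions and
amplifies regression noise by their ratio (observed to pin estimates at
the parameter bounds). A `defensive_weight` fraction (default 0.1) of
later-round simulations is drawn from the original prior, so an early
conditional-mean error cannot trap the sequence in the wrong region —
kept small because wide draws dilute the local regression.

## Benchmarks

*Direct mapping* returns the preprocessed SC with zero diagonal.
*Eigen-mapping* eigendecomposes the real SC Laplacian `I − C`, fits the
two-parameter map `λ_fc = exp(−λ_sc p1) + p2` by Nelder-Mead multistart
on the Lin loss of the reconstruction `U diag(·) Uᵀ` (no minmax during
fitting, which destroys convergence; metrics are computed on minmax
vectors like every method). With a zero-diagonal target `p2` is
unidentifiable (it only moves the diagonal), so only the reconstruction —
not `p2` — is meaningful. The returned matrix is minmax-rescaled into
[0, 1]; downstream metrics are invariant to that affine step.
*Coupled Wilson–Cowan*: one excitatory/inhibitory pair per region,
network input `K Σ_j c_ij E_j`, sigmoid `1/(1+e^{−1.5(x−3)})`, local
couplings (16, 12, 15, 3) and time constants (2.5, 3.75 ms) from the
standard open implementation of this model (the source publication defers
these constants; all are config-exposed). Euler–Maruyama at dt = 0.1 ms
(dt ≤ τ/5 enforced), 1 s burn-in, 61 s default duration with a
desk-scale preset (2–5 s, dt 0.2–0.25 ms) used in tests. The four global
parameters (K, P0, Q0, σ) are fitted by differential evolution on the Lin
loss with a fixed simulation seed so the objective is deterministic.

## Metrics and nulls

Pearson, Lin concordance (population moments), and MSE are computed on
minmax-scaled upper-triangle vectors (row-major — the canonical ordering
everywhere). Lin and MSE are additionally standardized against a null of
1000 region-identity permutations of the empirical FC (joint row/column
permutation — preserving the value distribution while destroying
topography); a spin null is available when per-region coordinates are
supplied (random 3-D rotation of the unit-sphere projections, optimal
one-to-one reassignment via linear sum assignment). Regional evaluation
computes per-column Pearson correlations, standardizes per region against
the null, and tests them against zero across subjects/replicates with a
one-sample t-test at the Bonferroni cutoff `−ln(0.05/N)` (≈ 7.2 for 68
regions).

## Synthetic study conditions

The generator emulates an atlas-level DTI connectome: two hemispheres of
N/2 regions, 3-D centroids in two clusters (70 mm separation, 24.5 mm
spread) giving Euclidean distances in the 20–150 mm range; Bernoulli
connections (densities 0.6 intra-, 0.25 inter-hemispheric) with
log-normal weights (σ = 1.0 — tractography weights span orders of
magnitude, which is what makes the capping step meaningful) times an
exponential distance decay (length scale 45 mm, as for streamline
counts); homolog pairs always connected; a within-hemisphere chain
guarantees no isolated region. Default N = 16 for fast tests; an N = 68
preset mirrors the atlas scale. What the generator does **not** emulate:
anatomical tract geometry, realistic degree sequences, measurement
(leakage/beamformer) structure of real MEG — so passing tests demonstrate
internal consistency of the pipeline, not field performance on real data.

Observations are model band FC plus i.i.d. Gaussian noise mirrored across
the upper triangle (so the per-entry noise sd is exact), clipped to
[0, 1]. Time series realize `X(ω) = UΓU^H P(ω)` on the FFT grid with
circular complex white `P`, Hermitian-symmetrized (real DC and Nyquist
bins) so the inverse transform is real-valued.

**Default operating point.** `DEFAULT_PARAMS = (τ_g = 0.006 s, v = 18 m/s,
α = 0.9)`: posterior modes reported for resting-state MEG place τ_g near
its 0.005 s lower bound, v near 20 m/s and α near 0.9; the defaults are
those values nudged strictly inside the admissible box. Recovery
experiments use `θ* = (0.015, 12, 0.5)` — a distinct, interior point.

**Participation energy** is `|diag(U^H F U)|` with harmonics evaluated at
the band's centre frequency (band centres 2.75, 5.5, 10.0, 16.5 Hz; the
alpha band defaults to 8–12 Hz, the 8–13 Hz variant is available).
Analyses restore the unit self-coherence diagonal before projecting: a
zero-diagonal FC has zero trace, which forces the signed projections to
cancel and pins the top-harmonic share at ~one half regardless of
structure. Concentration of FC energy in the first three harmonics is
strongest at low bands (where `|γ_k|² ∝ 1/|λ_k|²`) and weakens toward
beta, where the mode filter peaks at intermediate eigenvalue moduli; the
headline parsimony check is therefore stated for the delta band, and the
qualitative decay (first harmonic maximal, positive exponential decay
rate) is checked for delta/theta/alpha.

## Problem sizes

Desk-scale defaults keep everything on one CPU: connectomes of 4–16
regions, recovery with 2 rounds × 300 simulations over 5 seeds,
Monte-Carlo validation with 20,000 draws, 240–600 s synthetic recordings,
Wilson–Cowan runs of 2–21 s with the evolutionary fit at 2 generations ×
small populations in tests. The paper-faithful settings (3 × 1000
simulations, 200 annealing iterations, 61 s Wilson–Cowan simulations,
1000-permutation nulls) are the package defaults.

## Known limitations

- The Gaussian conditional family cannot represent multimodal posteriors;
  on multimodal problems the reported density is a local approximation
  around the dominant mode found by annealing.
- Coherence-channel inference inherits multitaper estimator bias (see
  above); spatial leakage and source-reconstruction confounds of real MEG
  are out of scope.
- The closed-form CSD degrades with delay phase (non-orthonormal
  harmonics); predictions remain well-defined but are no longer the exact
  second-order statistics of the generative law at high `ω d / v`.
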