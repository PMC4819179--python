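# Methods

This note records the models, numerical choices and known limitations behind
kfakit, in the order a reader meets them: the DKI signal model and its
scalar metrics, the two-shell proxy, the synthetic tissue generator, the
evaluation experiments, and the numerics.

## Signal model and estimation

The package fits the b-quadratic cumulant expansion of the diffusion-MRI
log-signal,

    ln S(b, n̂) = ln S0 − b n_i n_j D_ij + (b²/6) MD² n_i n_j n_k n_l W_ijkl,

with b in ms/µm² and D in µm²/ms (units are fixed internally; s/mm² inputs
are converted at the I/O boundary). The estimation parameterization is
1 (ln S0) + 6 (unique D components) + 15 (the quartic block V = MD²·W as one
linear group) = 22 unknowns, which makes the log-domain problem exactly
linear. The default `nlls` method minimizes residuals of the exponentiated
model with scipy's trust-region-reflective solver (step/function tolerances
1e-10, at most 500 function evaluations), started from the linear solution
weighted by the normalized signal (an approximation of the inverse log-signal
noise sd). W is recovered as V/MD² using MD from the same fit. A `wls`
method — the signal-weighted linear log-domain fit — is provided for large
sweeps; on noise-free model data both recover D to ~1e-6 and W to ~1e-5
relative.

Signals are normalized to the mean b = 0 image before fitting. No positivity
or directional-kurtosis constraints are imposed; instead, voxels with a
negative diffusion eigenvalue or with min K(n̂) < −3/7 (the magnitude-signal
bound) are flagged in QC channels. Design validity requires ≥ 22
measurements, ≥ 3 distinct b-values including b = 0, and a rank-22 design
matrix; violations raise a design error before any optimization runs.

## Scalar metrics

* **MD** = tr(D)/3.
* **FA** = √(3/2)·std(λ)/rms(λ) with population normalization (divide by
  n = 3, no Bessel correction). Eigenvalues are not clipped at zero first;
  an all-zero tensor returns FA = 0 rather than NaN.
* **W̄** = spherical mean of W(n̂) = (Wxxxx + Wyyyy + Wzzzz + 2Wxxyy +
  2Wxxzz + 2Wyyzz)/5, exact and closed-form.
* **KFA** = ‖W − W̄·I⁽⁴⁾‖_F / ‖W‖_F. The Frobenius norm sums squares over
  all 81 Cartesian components (multiplicity weights 1/4/6/12 over the 15
  unique values), which makes KFA rotation invariant; W̄·I⁽⁴⁾ is the
  orthogonal projection of W onto the isotropic direction, so KFA ∈ [0, 1]
  by construction. ‖W‖ = 0 returns KFA = 0 so that vanishing kurtosis does
  not poison maps.
* **MK** is computed as the numerical spherical average of the apparent
  kurtosis K(n̂) = (MD²/D(n̂)²)·W(n̂) rather than through the closed
  elliptic-integral form: MK serves only as a comparison metric here and
  quadrature error is far below fit noise. The default quadrature set is a
  packaged 1000-point Fibonacci-sphere set nudged (max displacement < 4e-4)
  to reproduce the exact degree-4 sphere moments; on isotropic D the
  quadrature is then exact to machine precision, and MK's rotation
  dependence on tissue-scale tensors is < 3e-4. A 256-point
  electrostatic-repulsion set is also packaged (as a sampling scheme); it
  was measured at ~1e-3 rotation error for MK, which motivated the denser
  default.

## Two-shell proxy

For two shells 0 < b₁ < b₂ sharing one direction set, inverting the
expansion per direction gives closed-form D(n̂) and K(n̂) (see README). The
KFA proxy is std(K)/rms(K) over directions, population-normalized — the same
std/rms structure as FA, applied to apparent kurtosis samples. Properties:
proxy ≤ 1 always (std ≤ rms); equal K values give 0. Numerical conventions:
b₁ = b₂ is rejected as a singular inversion; directions with non-positive
signals or D(n̂) ≤ 1e-12 are masked rather than voiding the voxel; negative
K values are retained in the statistic (discarding them would bias the proxy
upward); an rms below 1e-10 is treated as exactly zero kurtosis (roundoff of
the log inversion) so Gaussian voxels map to proxy = 0; fewer than 3 valid
directions is an error (per-voxel invalidity in maps). No calibration from
proxy values to KFA values is attempted — the two ranges are not expected to
coincide, only to correlate.

## Synthetic tissue generator

Voxels are mixtures of axially symmetric Gaussian compartments, for which
the DKI cumulants are exact and closed-form:

    D = Σ f_c D⁽ᶜ⁾,   W = (3/MD²)·FullSym[Σ f_c D⁽ᶜ⁾⊗D⁽ᶜ⁾ − D⊗D],

satisfying K(n̂) = 3(Σ f_c D_c(n̂)² − D(n̂)²)/D(n̂)² along every direction.
Exact ground truth is the point: every estimator in the package can be
tested against analytically known (D, W).

The population profiles emulate brain-like joint FA/KFA/MD marginals under
CSF-suppressed acquisition:

* **wm_like** — one dominant fiber bundle (40% of voxels add a minor
  crossing bundle at 5–25%), each bundle an intra-neurite stick
  (d∥ ∈ [1.8, 2.3], d⊥ ∈ [0.02, 0.15] µm²/ms, 35–60% of the bundle) plus an
  anisotropic hindered extracellular compartment (d∥ ∈ [1.4, 2.0],
  d⊥ ∈ [0.5, 0.9]), with up to 10% free isotropic water. The intra/extra
  perpendicular-diffusivity contrast produces WM-strength kurtosis
  (W̄ ~ 0.5–1) with high KFA (~0.8–0.95) and FA predominantly in the 0.6–1
  segmentation band.
* **gm_like** — 8–15 partially dispersed neurite sticks (Gaussian angular
  spread 0.5 about a main axis; 20–40% total), plus a slow isotropic pool
  (d ∈ [0.4, 0.7], cell-body-like) and a faster extracellular pool
  (d ∈ [1.0, 1.5]) whose diffusivity contrast adds isotropic-variance
  kurtosis. This keeps W̄ realistic while KFA stays low (~0.2–0.45) and FA
  lands predominantly in the 0.1–0.3 band.
* **mixed** — 40% WM-like, 40% GM-like, 20% strong multi-bundle crossings
  (low FA, high KFA). The resulting marginals: MD ≈ 0.7–1.1 µm²/ms, KFA
  mean ≈ 0.6 with sd ≈ 0.25 spanning ~0.1–0.95, and strong WM–GM KFA
  contrast — the feature the proxy correlation actually rides on.

What the generator does **not** emulate: water exchange between
compartments, diffusion-time dependence (only b and direction enter the
model), non-Gaussian compartmental signals (each compartment is exactly
Gaussian, so the true signal's higher cumulants are those of a finite
mixture), T2 differences between compartments, partial-volume CSF with fast
diffusivities (CSF suppression is assumed), and spatial correlation between
voxels. Consequently, passing correlation tests here show that the proxy
tracks KFA across a realistic *distribution of tensors under Rician noise*;
they do not certify behavior under exchange, long-diffusion-time or
acquisition-artifact effects in real scans.

Rician noise is applied as S → √((S + σg₁)² + (σg₂)²) with σ = S0/SNR (SNR
defined at b = 0) and per-realization generators derived from a seed and the
realization index, so any single realization is reproducible in isolation.
Infinite SNR takes a separate no-noise code path, never a large number.

## Experiments

* **Fiber mixing.** Signals from three orthogonal single-fiber kernels
  (default kernel: d∥ = 2.0, d⊥ = 0.4 µm²/ms fiber at 70% plus a 30%
  isotropic compartment at 1.0 µm²/ms, giving single-fiber FA ≈ 0.59 and
  KFA ≈ 0.92) are mixed with weights (1 − 2α, α, α), α from 0 to 1/3 in
  steps of 0.03, fitted with the DKI model, and tabulated against the
  volume-fraction index VI (the FA analogue on the fraction tensor). The
  9-direction proxy curve is computed from two-shell signals at b₁ = 1.0,
  b₂ = 2.4 ms/µm² synthesized from the same mixtures. Outcome: FA collapses
  (normalized FA ≈ 0.001 at VI = 0) while KFA survives (≈ 0.92) and MD
  stays flat within 2%.
* **Averaging phantom.** A 5×5×3 volume holds nine single-fiber bundles in
  a 3×3 grid (three bundles per axis) in free water (2.2 µm²/ms). Averaging
  each diffusion encoding across the bundle mask before fitting (mimicking
  one low-resolution voxel with orthogonal sub-voxel fibers) collapses FA
  (ratio < 0.05 of the voxel-wise mean), reduces KFA much less (ratio
  > 0.3), raises W̄ slightly, and moves MD < 3%. The default phantom shells
  are 0.5/1.0/1.8/2.5/3.0 ms/µm² × 15 directions — the top shell capped at
  3 because beyond it the truncated expansion's own bias on the averaged
  (six-compartment) signal starts to dominate the MD comparison.
* **Proxy sweeps.** For each (direction count, SNR) or (b₁, b₂) cell the
  sweep simulates b₀ + two shells from every voxel's exact tensors, adds
  Rician noise, computes per-voxel proxies, and averages the
  per-realization Pearson correlation with true KFA (mean of r over
  realizations, not r of pooled samples). Direction sets of size
  3/5/9/15/25/36/46/65/86 are seeded electrostatic-repulsion solutions
  shipped as text fixtures. Cells where more than half of the voxels fail
  are flagged. Default problem sizes — 1000 voxels and 100 noise
  realizations (500–1000 voxels and 25–100 realizations in the test suite)
  — were chosen because the realization-averaged correlations are already
  stable to ±0.01 at these sizes (doubling realizations moves cell means
  by well under 0.01).

At these conditions the package's own headline numbers (recomputed by
`scripts/acceptance.py` and the acceptance tests) are: mean r ≈ 0.81–0.88
for all cells with ≥ 9 directions at SNR 80–100 with b₁ = 1.0,
b₂ = 2.5 ms/µm²; r ≈ 0.85 for 9 directions at b₂ = 5.0 and SNR 100; r ≈ 0.9
for 86 directions at infinite SNR; monotone non-decreasing in both SNR and
direction count within Monte-Carlo tolerance.

## Numerical conventions and edge cases

* Degenerate inputs: FA of the zero tensor is 0; KFA of zero W is 0;
  D(n̂) ≤ 1e-12 raises a degenerate-direction error in `apparent_dk` and
  masks the direction in the proxy path.
* Tie-breaks: eigenvalues from `eigvalsh` are reported descending; the
  canonical hemisphere convention (z > 0, then y, then x) orders packaged
  direction sets deterministically.
* Rotation invariance: MD, FA, W̄, KFA are exact under rotation (to 1e-8 in
  tests); MK inherits the quadrature's < 3e-4 rotation dependence.
* Determinism: one seeded generator per experiment; sweep cells derive
  independent streams from (seed, cell index, realization) so results are
  bit-reproducible from the seed and configuration alone.

## Limitations

KFA and the proxy are estimated here only under the model's own forward
signal (plus Rician noise); model mismatch from real tissue (exchange, time
dependence, higher-order cumulants) is outside scope. The b-value grid
search extends to 6 ms/µm² where the quadratic expansion is a poor model of
real tissue signals — its results characterize the estimator, not tissue.
No outlier rejection, motion/eddy correction, or DICOM/BIDS handling is
provided.
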