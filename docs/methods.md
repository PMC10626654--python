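# Methods

## Model and assumptions

Each voxel's reciprocal-space map (RSM) at fixed |q| is treated as a smooth
function on the unit sphere obeying Friedel symmetry, and is represented by
an even-order band-limited expansion in *orthonormal real* spherical
harmonics. Coefficients are stored ℓ-major with m running −ℓ…+ℓ; the real
basis is built from the complex harmonics with the Condon–Shortley phase
folded in (Y_{ℓ,m>0} = √2(−1)^m Re Y_ℓ^m, Y_{ℓ,−m} = √2(−1)^m Im Y_ℓ^m).
Any self-consistent sign convention yields identical rotation invariants;
this one is recorded in every output container so that external code can
remap coefficients if it uses another convention.

The measurement model assumes:

- a narrow (pencil) beam, one ray per raster pixel through the pixel
  centre — beam width and divergence are not modelled;
- cubic voxels whose edge equals the scan step; the beam raster is centred
  on the volume, and the default raster parity is matched to the volume so
  that at axis-aligned angles beam positions coincide with voxel centres
  (a raster whose rays sit exactly on voxel faces leaves the outermost
  voxel layer unsampled);
- kinematic scattering integrated over azimuthal detector segments: each
  segment value is the integral of the RSM over an arc of the great circle
  orthogonal to the beam;
- no self-absorption and no per-projection intensity renormalization.

Beam direction u(α, β) = (cos α cos β, sin α cos β, sin β); the in-plane
axes e_j = (−sin α, cos α, 0) and e_k = u × e_j complete a right-handed
triple, and the detector azimuth φ = 0 lies along e_j. Rotations about axes
not orthogonal to the beam decompose into (α, β) plus in-plane transforms of
(j, k).

## Discretization and band limit

Azimuthal binning into N segments on [0, π) turns each great-circle cut into
N integrals of an even trigonometric polynomial. The bin-integration matrix
of the even frequencies {0, 2, …, M} has full column rank iff M ≤ N − 1
(`bin_sampling_matrix` makes this testable directly), so the fitted band
limit should satisfy ℓmax ≤ N − 1; with the default N = 8, ℓmax = 6. The
forward model warns, but does not refuse, when this is violated — phantoms
of higher band limit are deliberately not exactly recoverable and probe the
model-mismatch regime.

Arc integrals of the basis over each bin (the Y matrices) use fixed-order
Gauss–Legendre quadrature, order 16 per bin, which integrates the band
limits used here to below 1e-12; they are validated against dense trapezoid
quadrature in the tests.

## Projector

The John transform traverses the voxel grid with an Amanatides–Woo /
Siddon-style ray walk, weighting every traversed voxel by the exact length
of the intersecting ray segment; all coefficient channels share the
traversal. Bilinear slice-interpolation projectors are deliberately avoided
because treating each voxel's footprint as angle-independent introduces
high-frequency artifacts. The adjoint reuses the same weights, so the
dot-product identity ⟨Tx, y⟩ = ⟨x, Tᵀy⟩ holds to machine precision — a
prerequisite for exact gradients. Out-of-volume ray segments contribute
zero; rays whose constant coordinate lies exactly on the bounding plane are
treated as outside.

## Objective and solver

The objective is ‖P X Y − D‖²_F over valid pixels plus λ times the graph
Dirichlet energy Σ_{face pairs} ‖x_i − x_j‖² over 6-connected neighbours
(mirror boundaries, so constant fields incur zero penalty). Minimizing the
Dirichlet term maximizes the covariance between neighbouring RSMs. Residuals
are unweighted (plain least squares); masked detector pixels contribute
nothing. A single global λ multiplies the whole coefficient-space penalty;
no per-order weighting is applied.

The problem is a convex quadratic, solved with L-BFGS-B using the analytic
gradient (assembled via the adjoint projector and Yᵀ). Defaults: 200
iterations maximum, relative loss-change tolerance 1e-6, no non-negativity
constraint. When λ is not given it is set to
0.05 × (number of measured values) / (number of voxels), which balances the
growth of the two terms with problem size; the tests that probe exact
recovery pass a small explicit λ instead. Random initialization draws
i.i.d. uniform coefficients in [0, scale), with scale = 1e-3 × (mean data
value / mean chord length) — several orders of magnitude below the expected
coefficient magnitude, so different seeds converge to losses within 0.1 % of
each other (verified by test). `mode="rank2"` restricts the same solver to
ℓmax = 2, reproducing the symmetric rank-2 tensor model; for ℓmax = 2 data
the two modes agree in loss to well under 0.1 %.

## Invariant analysis

With the orthonormal basis, the cross-spectrum normalization is fixed to
N_ℓ = 1/(4π), which makes Σ_ℓ S_ℓ the literal sphere-surface average of the
product of two functions; mean, variance (anisotropic power), covariance,
relative anisotropy σ/ḡ and R² = cov²/(var·var) follow. Relative anisotropy
is normalized by the mean rather than the RMS so that it stays unbounded and
keeps contrast for strongly textured voxels. Voxels with non-positive mean
or zero variance return NaN and are excluded from summary statistics.

The ℓ = 2 orientation axis maps the five ℓ = 2 coefficients linearly onto
the symmetric traceless second-moment tensor (the map is computed once by
exact quadrature) and takes the eigenvector of the *distinct* eigenvalue —
the axis about which the ℓ = 2 part is closest to zonal, which is the fibre
axis for equatorial (fibre-symmetric) scattering and the pole for meridional
scattering. Signs are fixed to the positive-z hemisphere (ties: +x, then
+y); degenerate spectra are flagged and return an arbitrary vector of the
degenerate subspace.

The ensemble anisotropic power quotient is implemented as
Q = var(mean_i g_i) / mean_i var(g_i). Cauchy–Schwarz and Jensen give
Q ∈ [0, 1], with equality to 1 exactly when all members share the same
anisotropic part — the two properties that define the statistic.

Squared-representation expansions (needed to average squared-polynomial
reconstructions in the linear representation) sample the square on a
Driscoll–Healy equiangular grid with exact sampling-theorem weights, sized
so the product of the squared function (band 2ℓin) with the analysis basis
(band ℓout) is integrated exactly; the grid densifies automatically with
the band limits. The variance of an expanded square agrees with dense
quadrature to ~1e-13 relative, comfortably within the 0.1 % accuracy the
ensemble analysis requires.

Box-plot summaries use Tukey quartiles with whiskers spanning the extreme
observations inside [Q1 − 1.25·IQR, Q3 + 1.25·IQR]; the 1.25 factor is kept
deliberately, although 1.5 is the more common choice.

## Synthetic samples

The generator emulates millimetre-scale samples whose nanostructure
orientation varies smoothly between a few dominant texture domains:

1. source voxels placed by greedy maximin (farthest-point) sampling under
   the interior distance; the seeded random start voxel only initializes
   the sweep and is discarded, so e.g. two sources on a rod are its ends;
2. interior distances by Dijkstra on the 26-connected voxel graph with
   Euclidean edge weights (scipy.sparse.csgraph);
3. per-source spectra P(ℓ) ∝ (1+ℓ)^−1.5 over even orders (exponent
   exposed), with per-source amplitudes drawn uniformly in [0.5, 1.5];
4. every voxel's per-order power equals the Gaussian-kernel
   (k_s = exp(−d²/2L²)) distance-weighted average of the source powers;
   correlation with the nearest source is targeted at k_s — a Gaussian
   decay with the correlation length L as standard deviation (default:
   a quarter of the mask diameter); the decorrelated remainder comes from
   a Gaussian-filtered smooth random field, orthogonalized against the
   source mixture per order so the correlation target is not contaminated;
5. symmetry classes: `rank2` keeps ℓ ≤ 2; `high_order` (ℓmax = 8) sets
   P(2) = P(4), damping the rank-2 component the way RSMs with competing
   meridional/equatorial contributions do; `zonal` (ℓmax = 12) builds
   exactly zonal functions about a smoothly varying axis field (principal
   eigenvector of a kernel-weighted orientation tensor), with per-order
   signs chosen so the function peaks on the equatorial great circle —
   each source thereby correlates with the ℓ-weighted spherical delta
   about its axis, w(ℓ) = 1/(2ℓ+1) by default;
6. non-negativity enforced by raising only the isotropic coefficient until
   a dense quasi-uniform sampling (Fibonacci grid, ≥ 8(ℓmax+1)² points) of
   every voxel's function is non-negative; idempotent up to grid
   resolution.

This construction satisfies the stated constraints deterministically rather
than through an iterative penalized fit; it was chosen because it makes the
power and correlation targets hold by construction and keeps generation
fast and exactly reproducible from a seed.

Measurements add Gaussian noise with standard deviation
(mean nonzero signal)/SNR, clipped at zero (clip counts reported); a Poisson
option scales intensities so shot noise matches the requested SNR at the
mean. The default acquisition is two tilt series, β ∈ {0°, 45°}, with α
covering [0°, 180°) in 10° steps — 36 projections; dropping the tilted
series reproduces the classic missing-wedge degradation.

What the phantoms do *not* emulate: detector-level physics (form factors,
q-resolution, polarization), beam-size effects, self-absorption, alignment
errors, and the exact (unpublished) parameter values behind any particular
deposited dataset. Passing the recovery tests therefore demonstrates
correctness of the forward model, solver and metrics under the stated noise
model, not end-to-end fidelity to any specific experiment.

## Problem sizes and numerical choices

The validation studies run at desk scale: 16³ voxels, 36 projections,
8 bins. Canonical full-scale specs (50³ with 2–4 sources, 60×60×80 with 5)
are provided and use the identical code path; they simply take longer. The
noise study fits an ℓmax = 6 model to an ℓmax = 12 zonal phantom at four
SNR levels (40, 15, 8, 4) — reconstruction quality degrades monotonically,
with median R² around 0.6–0.63 bounded by the deliberate band-limit
mismatch and the two-tilt wedge; a rank-2 fit of a high-order phantom is
capped near R² ≈ 0.26 versus ≈ 0.68 for the full model. R² between fields
of different band limits zero-pads the narrower field: truncating the
reference instead would discard reference variance and inflate the score.

Degenerate inputs: non-unit directions, improper rotations, overlapping
bins, NaN data without a mask, negative λ and shape mismatches raise
ValueError with a diagnostic; undefined statistics return NaN sentinels
rather than raising.

## Known limitations

- Single-threaded CPU projector (numba); no GPU kernels.
- No per-projection alignment refinement; geometry is taken as exact.
- The ℓ-weighted zonal construction attenuates parts of the equatorial
  ring where continuity and zonality compete, so zonal phantoms are only
  approximately zonal near domain boundaries — by design.
- The mapping between this package's SNR definition and that of any
  external dataset is not calibrated; absolute SNR labels are comparable
  only within this package.
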