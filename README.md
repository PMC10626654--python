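# sigtt — spherical integral geometric tensor tomography

`sigtt` reconstructs the three-dimensional **reciprocal-space map** (RSM) of
every voxel in a sample from azimuthally binned scanning small-angle X-ray
scattering (SAXS) projections taken at multiple rotations and tilts — the
inverse problem of SAXS **tensor tomography** (SAXSTT). It is aimed at
researchers studying volume-resolved nanostructure orientation and texture in
materials such as bone, collagen, polymers and fibre composites.

## The model

The RSM of voxel **r** at fixed |q| is a function on the unit sphere. Friedel
symmetry, I(q) = I(−q), restricts it to even spherical-harmonic orders, so it
is modelled as a band-limited expansion

    f(r, n) = Σ_{ℓ even ≤ ℓmax} Σ_m  a_ℓ^m(r) Y_ℓ^m(n)

in orthonormal real spherical harmonics. One pencil-beam exposure at rotation
(α, β) and raster offset (j, k) measures line integrals of f along the beam
(the John / X-ray transform P), restricted to the great circle of directions
orthogonal to the beam, integrated over N azimuthal detector segments (the
circle-bin matrix Y). Collecting voxel coefficients into a matrix X, the data
stack D obeys the *linear* system

    D = P X Y,

and the reconstruction solves the convex problem

    argmin_X  ‖P X Y − D‖² + λ Σ_{neighbours (i,j)} ‖x_i − x_j‖²

with a limited-memory quasi-Newton method. The linearity — no squaring of the
polynomial, no per-voxel Euler angles — is what distinguishes this approach
from zonal-harmonics (ZH) squared-polynomial fitting; the symmetric rank-2
tensor model of iterative-reconstruction (IR) codes is available as the
`mode="rank2"` (ℓmax = 2) restriction of the same solver.

With N azimuthal bins on [0, π), a great-circle cut is a trigonometric
polynomial with even frequencies up to N − 1, so ℓmax ≤ N − 1 is the largest
uniquely recoverable band limit: for the standard N = 8, ℓmax = 6
(28 coefficients per voxel).

Reconstructions are analysed with rotation invariants built from the
cross-spectrum S_ℓ(g, h) = (1/4π) Σ_m c_ℓ^m(g) c_ℓ^m(h): spherical mean,
anisotropic power var(g) = Σ_{ℓ≥2} S_ℓ, relative anisotropy σ(g)/ḡ, the
squared Pearson correlation R² = cov²/(var·var) against a reference, the
ℓ = 2 fibre orientation axis, and the ensemble anisotropic power quotient
Q = var(mean_i g_i) / mean_i var(g_i), which is 1 exactly when an ensemble of
reconstructions with randomized initial conditions agrees.

A synthetic-sample generator produces textured phantoms of three symmetry
classes (approximately zonal ℓmax = 12, rank-2, and high-order ℓmax = 8 with
damped ℓ = 2) and their noisy binned measurements, for validation end to end.

## Worked example

```python
import sigtt

spec = sigtt.PhantomSpec((16, 16, 16), symmetry_class="rank2", n_sources=2, seed=3)
truth = sigtt.synthesize_field(spec)                      # ground-truth RSM field
geometry = sigtt.default_acquisition((16, 16, 16))        # 2 tilt series, 36 projections
data = sigtt.simulate_measurements(truth, geometry, snr=20.0, seed=0)

model = sigtt.SAXSTensorTomography(data, geometry, ell_max=2)
results = model.fit(max_iter=300)
print(results.summary(reference=truth))
```

prints

```
SAXS tensor tomography reconstruction
=====================================================
volume shape        : (16, 16, 16)
band limit ell_max  : 2 (6 coefficients/voxel)
projections         : 36
azimuthal bins      : 8
lambda (smoothness) : 2.756
iterations          : 30 (converged: True)
final loss          : 13284.6
non-empty voxels    : 3865
relative anisotropy : median 0.466 (IQR 0.424-0.761)
R^2 vs reference    : median 0.973 (IQR 0.951-0.986)
```

i.e. at signal-to-noise ratio 20 the fitted per-voxel RSMs correlate with the
simulated truth at a median R² of 0.97 inside the sample support; λ was set
by the data-scaled heuristic. `results.invariant_maps()` returns the voxel
maps behind these summaries, `model.fit_ensemble(n_runs=10)` adds the Q map,
and `results.save("recon.h5")` writes the HDF5 container.

The same pipeline is available from the shell:

```sh
sigtt simulate phantom.h5 --shape 16 16 16 --symmetry rank2 --snr 20
sigtt reconstruct phantom.h5 recon.h5 --ell-max 6
sigtt analyze recon.h5 --report report.csv
sigtt ensemble phantom.h5 ens.h5 --n-runs 10
```

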