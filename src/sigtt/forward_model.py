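"""Forward model D = P X Y, regularizer and gradients.

The measured data form a stack D of azimuthally binned intensities,
one (n_j x n_k x N_bins) raster per projection.  The model composes the
John transform P (line integrals of each coefficient channel) with the
per-projection circle-bin matrix Y (arc integrals of the basis over the
probed great circle), and the reconstruction minimizes

    ||P X Y - D||^2  +  lambda * sum_{neighbours (i,j)} ||x_i - x_j||^2

The second term is the graph Dirichlet energy of the coefficient field
over 6-connected voxel faces - the squared discrete Laplacian
smoothness penalty; minimizing it maximizes the covariance between
neighbouring reciprocal-space maps.  Boundaries are mirrored, so a
spatially constant field incurs zero penalty.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .basis import BasisConvention, circle_bin_coefficients
from .geometry import ProjectionGeometry
from .projector import CoefficientVolume, john_adjoint, john_transform

__all__ = [
    "AzimuthalBinning",
    "BinnedMeasurement",
    "predict",
    "laplacian_penalty",
    "loss_and_gradient",
    "bin_sampling_matrix",
]


@dataclass(frozen=True)
class AzimuthalBinning:
    """N contiguous azimuthal bins tiling [0, pi) (Friedel half-circle)."""

    n_bins: int = 8

    @property
    def bin_width(self) -> float:
        return np.pi / self.n_bins

    @property
    def bin_centers(self) -> np.ndarray:
        return (np.arange(self.n_bins) + 0.5) * self.bin_width

    def matrices(self, geometry: ProjectionGeometry, convention: BasisConvention):
        """Per-projection (M x N_bins) circle-bin matrices Y."""
        return np.stack(
            [
                circle_bin_coefficients(
                    geometry.alphas[i],
                    geometry.betas[i],
                    self.bin_centers,
                    self.bin_width,
                    convention,
                )
                for i in range(geometry.n_projections)
            ]
        )


@dataclass
class BinnedMeasurement:
    """Stack of segment-integrated intensities with their binning.

    data has shape (n_projections, n_j, n_k, N_bins).  ``mask`` (same
    shape, boolean) marks valid entries; invalid ones contribute zero
    residual and zero gradient.
    """

    data: np.ndarray
    binning: AzimuthalBinning = field(default_factory=AzimuthalBinning)
    mask: Optional[np.ndarray] = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4 or self.data.shape[-1] != self.binning.n_bins:
            raise ValueError(
                "data must have shape (n_projections, n_j, n_k, "
                f"{self.binning.n_bins})"
            )
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.data.shape:
                raise ValueError("mask shape must match data shape")


def predict(
    volume: CoefficientVolume,
    geometry: ProjectionGeometry,
    binning: AzimuthalBinning,
    bin_matrices: Optional[np.ndarray] = None,
) -> BinnedMeasurement:
    """Model data for a coefficient volume: John transform then Y contraction."""
    import warnings

    if volume.convention.ell_max > binning.n_bins - 1:
        warnings.warn(
            f"ell_max={volume.convention.ell_max} exceeds the band limit "
            f"N_bins - 1 = {binning.n_bins - 1} uniquely constrained by "
            f"{binning.n_bins} azimuthal bins",
            stacklevel=2,
        )
    if bin_matrices is None:
        bin_matrices = binning.matrices(geometry, volume.convention)
    proj = john_transform(volume, geometry)  # (P, nj, nk, M)
    out = np.einsum("pjkm,pmn->pjkn", proj, bin_matrices)
    return BinnedMeasurement(out, binning)


def laplacian_penalty(volume: CoefficientVolume, lam: float):
    """Dirichlet smoothness energy and its gradient.

    value = lam * sum over face-adjacent voxel pairs of ||c_i - c_j||^2;
    gradient[i] = 2 lam * sum_{j ~ i} (c_i - c_j).
    """
    if lam < 0:
        raise ValueError("regularization weight lambda must be >= 0")
    v = volume.values
    value = 0.0
    grad = np.zeros_like(v)
    for axis in range(3):
        d = np.diff(v, axis=axis)
        value += float(np.sum(d * d))
        pad = [(0, 0)] * 4
        pad[axis] = (1, 1)
        dp = np.pad(d, pad)  # zero-flux (mirror) boundaries
        sl_lo = [slice(None)] * 4
        sl_hi = [slice(None)] * 4
        sl_lo[axis] = slice(0, v.shape[axis])
        sl_hi[axis] = slice(1, v.shape[axis] + 1)
        grad += 2.0 * (dp[tuple(sl_hi)] - dp[tuple(sl_lo)]) * -1.0
    return lam * value, lam * grad


def loss_and_gradient(
    volume: CoefficientVolume,
    data: BinnedMeasurement,
    geometry: ProjectionGeometry,
    lam: float = 0.0,
    bin_matrices: Optional[np.ndarray] = None,
):
    """Regularized least-squares objective and its exact gradient.

    loss = ||predict(X) - D||_F^2 over valid pixels + Dirichlet penalty;
    the data-term gradient is assembled through the adjoint projector
    and the transposed circle-bin matrices.
    """
    if data.mask is None and np.isnan(data.data).any():
        raise ValueError("data contain NaN values without a validity mask")
    if bin_matrices is None:
        bin_matrices = data.binning.matrices(geometry, volume.convention)
    model = predict(volume, geometry, data.binning, bin_matrices)
    resid = model.data - data.data
    if data.mask is not None:
        resid = np.where(data.mask, resid, 0.0)
    loss = float(np.sum(resid * resid))
    back = np.einsum("pjkn,pmn->pjkm", resid, bin_matrices)
    grad = 2.0 * john_adjoint(back, geometry)
    if lam > 0:
        pen, pen_grad = laplacian_penalty(volume, lam)
        loss += pen
        grad += pen_grad
    elif lam < 0:
        raise ValueError("regularization weight lambda must be >= 0")
    return loss, grad


def bin_sampling_matrix(n_bins: int, ell_max: int) -> np.ndarray:
    """Linear map from even circle-Fourier coefficients to bin integrals.

    On the probed great circle an even band-limited function is a
    trigonometric polynomial with frequencies m in {0, 2, ..., ell_max}
    (odd frequencies vanish by Friedel symmetry), i.e. M = ell_max + 1
    real coefficients.  Row i of the returned (n_bins x M) matrix
    integrates [1, cos 2t, sin 2t, cos 4t, ...] over bin i of [0, pi).
    Full column rank iff ell_max <= n_bins - 1: the Nyquist rule that
    caps the recoverable band limit at N - 1 for N bins.
    """
    if ell_max % 2 != 0:
        raise ValueError("ell_max must be even")
    width = np.pi / n_bins
    centers = (np.arange(n_bins) + 0.5) * width
    cols = [np.full(n_bins, width)]
    for m in range(2, ell_max + 1, 2):
        lo, hi = centers - width / 2, centers + width / 2
        cols.append((np.sin(m * hi) - np.sin(m * lo)) / m)
        cols.append((np.cos(m * lo) - np.cos(m * hi)) / m)
    return np.stack(cols, axis=1)
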