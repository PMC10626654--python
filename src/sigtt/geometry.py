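"""Projection-space geometry.

A tensor-tomography measurement is indexed by four coordinates
(j, k, alpha, beta): the raster offsets of the pencil beam in the plane
of projection and the two rotation angles of the sample.  The beam
direction is

    u(alpha, beta) = (cos a cos b, sin a cos b, sin b)

with alpha the azimuthal and beta the polar (tilt) angle relative to a
fixed sample-frame plane.  (e_j, e_k, u) form a right-handed orthonormal
triple; j maps to e_j, k to e_k, and the detector azimuth phi = 0 is
aligned with e_j.  Rotations about axes not orthogonal to the beam
decompose into (alpha, beta) plus in-plane transforms of (j, k).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ProjectionGeometry", "basis_vectors", "great_circle_points"]


def basis_vectors(alpha: float, beta: float):
    """Beam direction u and projection-plane axes (e_j, e_k)."""
    ca, sa = np.cos(alpha), np.sin(alpha)
    cb, sb = np.cos(beta), np.sin(beta)
    u = np.array([ca * cb, sa * cb, sb])
    e_j = np.array([-sa, ca, 0.0])
    e_k = np.array([-ca * sb, -sa * sb, cb])
    return u, e_j, e_k


def great_circle_points(alpha: float, beta: float, phi_values) -> np.ndarray:
    """Points C(phi) = cos(phi) e_j + sin(phi) e_k on the probed great circle.

    The set of reciprocal-space directions visible in one exposure is
    the great circle orthogonal to the beam; C(phi) . u = 0 for all phi
    and C(phi + pi) = -C(phi).
    """
    _, e_j, e_k = basis_vectors(alpha, beta)
    phi = np.atleast_1d(np.asarray(phi_values, dtype=float))
    return np.cos(phi)[:, None] * e_j + np.sin(phi)[:, None] * e_k


@dataclass
class ProjectionGeometry:
    """Ordered projection list plus raster and volume metadata.

    alphas/betas are radians, one entry per projection.  The raster is
    (n_j, n_k) beam positions spaced one voxel apart (cubic voxels of
    the same size as the scan step), centred on the volume.
    """

    alphas: np.ndarray
    betas: np.ndarray
    raster_shape: tuple
    volume_shape: tuple
    voxel_size: float = 1.0

    def __post_init__(self):
        self.alphas = np.atleast_1d(np.asarray(self.alphas, dtype=float))
        self.betas = np.atleast_1d(np.asarray(self.betas, dtype=float))
        if self.alphas.shape != self.betas.shape:
            raise ValueError("alphas and betas must have equal length")
        self.raster_shape = tuple(int(n) for n in self.raster_shape)
        self.volume_shape = tuple(int(n) for n in self.volume_shape)
        if len(self.raster_shape) != 2 or len(self.volume_shape) != 3:
            raise ValueError("raster_shape must be 2-D and volume_shape 3-D")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")

    @property
    def n_projections(self) -> int:
        return self.alphas.size

    def basis_vectors(self, i: int):
        return basis_vectors(self.alphas[i], self.betas[i])

    def raster_offsets(self):
        """Centred (j, k) offsets of each raster pixel, in voxel units."""
        n_j, n_k = self.raster_shape
        j = np.arange(n_j) - (n_j - 1) / 2.0
        k = np.arange(n_k) - (n_k - 1) / 2.0
        return j, k


def default_acquisition(
    volume_shape,
    raster_shape=None,
    tilts_deg=(0.0, 45.0),
    alpha_step_deg: float = 10.0,
    voxel_size: float = 1.0,
) -> ProjectionGeometry:
    """Two-tilt-series acquisition: alpha in [0, 180) per tilt beta.

    The default (beta in {0, 45} deg, 10 deg alpha steps) gives 36
    projections; a single-tilt variant exhibits the classic missing
    wedge.  Raster defaults to the largest volume cross-section.
    """
    if raster_shape is None:
        n = int(np.ceil(np.linalg.norm(volume_shape)))
        # match raster parity to the volume so that at axis-aligned
        # angles the beam positions hit voxel centres, never edges
        if n % 2 != max(volume_shape) % 2:
            n += 1
        raster_shape = (n, n)
    alphas, betas = [], []
    for b in tilts_deg:
        for a in np.arange(0.0, 180.0, alpha_step_deg):
            alphas.append(np.deg2rad(a))
            betas.append(np.deg2rad(b))
    return ProjectionGeometry(
        np.array(alphas), np.array(betas), raster_shape, tuple(volume_shape), voxel_size
    )
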