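"""Real, even-order spherical-harmonic basis.

Reciprocal-space maps in small-angle scattering obey Friedel symmetry,
I(q) = I(-q), so only even harmonic orders carry signal.  Everything in
this package therefore works with a band-limited expansion

    f(n) = sum_{l even <= ell_max} sum_{m=-l..l} c_l^m Y_l^m(n)

in *orthonormal real* spherical harmonics: the Gram matrix of the basis
under the uniform sphere measure is the identity.  Coefficients are
stored l-major, with m running from -l to +l within each order.

The real basis is built from scipy's complex harmonics with the
Condon-Shortley phase folded in::

    Y_{l,0}  = Y_l^0
    Y_{l,m}  = sqrt(2) (-1)^m Re Y_l^m      (m > 0)
    Y_{l,-m} = sqrt(2) (-1)^m Im Y_l^m      (m > 0)

Any self-consistent sign convention gives identical invariants; this one
is recorded in output containers for interoperability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import sph_harm_y

__all__ = [
    "BasisConvention",
    "evaluate_basis",
    "circle_bin_coefficients",
    "zonal_delta_coefficients",
    "rotate_expansion",
    "quadrature_grid",
    "expand_samples",
    "driscoll_healy_grid",
]


@dataclass(frozen=True)
class BasisConvention:
    """Band limit and coefficient ordering of the even-order real basis.

    Parameters
    ----------
    ell_max
        Even band limit; orders l in {0, 2, ..., ell_max} are included.
    """

    ell_max: int
    orders: tuple = field(init=False, repr=False)

    def __post_init__(self):
        if self.ell_max < 0 or self.ell_max % 2 != 0:
            raise ValueError(f"ell_max must be a non-negative even integer, got {self.ell_max}")
        lm = tuple(
            (l, m) for l in range(0, self.ell_max + 1, 2) for m in range(-l, l + 1)
        )
        object.__setattr__(self, "orders", lm)

    @property
    def n_coeffs(self) -> int:
        # (L+1)(L+2)/2 for even-only orders: 1, 6, 15, 28, ...
        return len(self.orders)

    def order_slices(self) -> dict[int, slice]:
        """Slice into a coefficient vector for each order l."""
        out, i = {}, 0
        for l in range(0, self.ell_max + 1, 2):
            out[l] = slice(i, i + 2 * l + 1)
            i += 2 * l + 1
        return out

    def describe(self) -> dict:
        return {
            "ell_max": self.ell_max,
            "orders": "even only",
            "ordering": "l-major, m from -l to +l",
            "normalization": "orthonormal real (Condon-Shortley phased tesseral)",
        }


def _check_directions(directions: np.ndarray) -> np.ndarray:
    directions = np.atleast_2d(np.asarray(directions, dtype=float))
    if directions.shape[-1] != 3:
        raise ValueError("directions must have shape (n, 3)")
    norms = np.linalg.norm(directions, axis=-1)
    bad = np.abs(norms - 1.0) > 1e-9
    if np.any(bad):
        worst = float(np.abs(norms - 1.0).max())
        raise ValueError(
            f"{int(bad.sum())} direction(s) are not unit-norm "
            f"(max |norm - 1| = {worst:.3e})"
        )
    return directions


def evaluate_basis(directions, convention: BasisConvention) -> np.ndarray:
    """Evaluate every basis function at unit direction vectors.

    Returns an (n_directions, M) matrix; column order follows the
    convention's (l, m) enumeration.
    """
    directions = _check_directions(directions)
    x, y, z = directions[:, 0], directions[:, 1], directions[:, 2]
    theta = np.arccos(np.clip(z, -1.0, 1.0))
    phi = np.arctan2(y, x)
    out = np.empty((directions.shape[0], convention.n_coeffs))
    sqrt2 = np.sqrt(2.0)
    for col, (l, m) in enumerate(convention.orders):
        if m == 0:
            out[:, col] = sph_harm_y(l, 0, theta, phi).real
        elif m > 0:
            out[:, col] = sqrt2 * (-1) ** m * sph_harm_y(l, m, theta, phi).real
        else:
            out[:, col] = sqrt2 * (-1) ** m * sph_harm_y(l, -m, theta, phi).imag
    return out


def circle_bin_coefficients(
    alpha: float,
    beta: float,
    bin_centers: np.ndarray,
    bin_width: float,
    convention: BasisConvention,
    quad_order: int = 16,
) -> np.ndarray:
    """Integrals of each basis function over azimuthal arcs of a great circle.

    One scanning-SAXS exposure probes the great circle orthogonal to the
    beam direction u(alpha, beta); azimuthal binning of the detector
    integrates the reciprocal-space map over arcs of that circle.  The
    returned (M, N_bins) matrix Y maps per-voxel coefficients to
    per-bin contributions: entry (c, i) is the integral of basis
    function c over [phi_i - dphi/2, phi_i + dphi/2] along
    C(tau) = cos(tau) e_j + sin(tau) e_k.

    Bins must tile [0, pi) without overlap (Friedel symmetry makes the
    other half circle redundant).  Fixed-order Gauss-Legendre quadrature
    per bin; order 16 integrates the band limits used here to < 1e-12.
    """
    from .geometry import basis_vectors

    bin_centers = np.asarray(bin_centers, dtype=float)
    n_bins = bin_centers.size
    if not np.isclose(n_bins * bin_width, np.pi, rtol=1e-9):
        raise ValueError(
            f"{n_bins} bins of width {bin_width} do not tile [0, pi)"
        )
    edges = np.sort(bin_centers - bin_width / 2)
    gaps = np.diff(edges)
    if np.any(np.abs(gaps - bin_width) > 1e-9):
        raise ValueError("bins overlap or leave gaps in [0, pi)")

    _, e_j, e_k = basis_vectors(alpha, beta)
    nodes, weights = np.polynomial.legendre.leggauss(quad_order)
    out = np.empty((convention.n_coeffs, n_bins))
    for i, center in enumerate(bin_centers):
        tau = center + 0.5 * bin_width * nodes
        dirs = np.cos(tau)[:, None] * e_j + np.sin(tau)[:, None] * e_k
        vals = evaluate_basis(dirs, convention)  # (quad_order, M)
        out[:, i] = 0.5 * bin_width * (weights @ vals)
    return out


def zonal_delta_coefficients(
    direction, weights, convention: BasisConvention
) -> np.ndarray:
    """l-weighted spherical delta function aimed along ``direction``.

    Coefficient (l, m) equals w(l) * Y_l^m(direction), which is the
    band-limited, l-reweighted delta peaked at the direction; it is
    zonally symmetric about that axis.  ``weights`` holds one w(l) per
    even order 0, 2, ..., ell_max.
    """
    direction = _check_directions(direction)[0]
    weights = np.asarray(weights, dtype=float)
    n_orders = convention.ell_max // 2 + 1
    if weights.size != n_orders:
        raise ValueError(
            f"need {n_orders} weights (one per even order), got {weights.size}"
        )
    row = evaluate_basis(direction[None, :], convention)[0]
    coeffs = row.copy()
    for l, sl in convention.order_slices().items():
        coeffs[sl] *= weights[l // 2]
    return coeffs


# --- quadrature grids -----------------------------------------------------

def quadrature_grid(ell_max: int):
    """Gauss-Legendre x uniform-azimuth product grid exact for band 2*ell_max.

    Returns (directions (n, 3), weights (n,)); weights sum to 4*pi.
    Integrates any spherical polynomial of degree <= 2*ell_max + 1
    exactly, which makes analysis of products f*g of two band-ell_max
    functions exact.
    """
    n_theta = ell_max + 1
    n_phi = 2 * ell_max + 1
    x, w = np.polynomial.legendre.leggauss(n_theta)
    phi = np.arange(n_phi) * 2 * np.pi / n_phi
    ct, pp = np.meshgrid(x, phi, indexing="ij")
    st = np.sqrt(1.0 - ct**2)
    dirs = np.stack(
        [st * np.cos(pp), st * np.sin(pp), ct], axis=-1
    ).reshape(-1, 3)
    wt = np.repeat(w, n_phi) * (2 * np.pi / n_phi)
    return dirs, wt


def expand_samples(
    samples: np.ndarray,
    directions: np.ndarray,
    weights: np.ndarray,
    convention: BasisConvention,
) -> np.ndarray:
    """Project sampled function values onto the basis by quadrature.

    c = sum_i w_i f(d_i) Y(d_i); exact when the quadrature integrates
    f * Y exactly. ``samples`` may carry leading batch axes.
    """
    basis = evaluate_basis(directions, convention)
    return np.asarray(samples) * np.asarray(weights) @ basis


def rotate_expansion(coefficients: np.ndarray, rotation: np.ndarray) -> np.ndarray:
    """Rotate a band-limited expansion: (R.f)(n) = f(R^T n).

    Uses exact quadrature re-expansion rather than Wigner-D recursions:
    the rotated function is sampled on a grid exact for the band limit
    and re-projected.  Exact to quadrature round-off (~1e-13) for any
    proper rotation. ``coefficients`` may carry leading batch axes.
    """
    rotation = np.asarray(rotation, dtype=float)
    if rotation.shape != (3, 3) or not (
        np.allclose(rotation @ rotation.T, np.eye(3), atol=1e-9)
        and abs(np.linalg.det(rotation) - 1.0) < 1e-9
    ):
        raise ValueError("rotation must be a proper (det=+1) orthogonal 3x3 matrix")
    coefficients = np.asarray(coefficients, dtype=float)
    M = coefficients.shape[-1]
    ell_max = _ell_max_from_n_coeffs(M)
    conv = BasisConvention(ell_max)
    dirs, wts = quadrature_grid(ell_max)
    samples = coefficients @ evaluate_basis(dirs @ rotation, conv).T
    return expand_samples(samples, dirs, wts, conv)


def _ell_max_from_n_coeffs(n: int) -> int:
    l = 0
    while (l + 1) * (l + 2) // 2 < n:
        l += 2
    if (l + 1) * (l + 2) // 2 != n:
        raise ValueError(f"{n} is not a valid even-order coefficient count")
    return l


def driscoll_healy_grid(bandwidth: int):
    """Equiangular Driscoll-Healy grid with exact sampling-theorem weights.

    For band limit B (all orders l < B resolved) the grid has 2B polar
    rings theta_j = pi*j/(2B) and 2B azimuthal points, with ring weights

        w_j = (2 pi / B^2) sin(theta_j) sum_{p<B} sin((2p+1) theta_j)/(2p+1)

    so that sum w_j f(d_j) integrates any spherical polynomial of degree
    < 2B exactly over the sphere.  Returns (directions, weights).
    """
    B = int(bandwidth)
    if B < 1:
        raise ValueError("bandwidth must be >= 1")
    j = np.arange(2 * B)
    theta = np.pi * j / (2 * B)
    p = np.arange(B)
    ring = np.sin(theta)[:, None] * np.sin(np.outer(theta, 2 * p + 1)) / (2 * p + 1)
    w_theta = (2.0 / B) * ring.sum(axis=1)  # integrates sin(theta) dtheta exactly
    phi = np.arange(2 * B) * (np.pi / B)
    tt, pp = np.meshgrid(theta, phi, indexing="ij")
    dirs = np.stack(
        [np.sin(tt) * np.cos(pp), np.sin(tt) * np.sin(pp), np.cos(tt)], axis=-1
    ).reshape(-1, 3)
    wts = np.repeat(w_theta * (np.pi / B), 2 * B)
    return dirs, wts
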