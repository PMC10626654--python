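"""Rotation-invariant analysis of spherical-function fields.

Comparisons of reciprocal-space maps must not depend on the sample
coordinate system, so every statistic here is built from the
cross-spectrum

    S_l(g, h) = N_l * sum_m c_l^m(g) c_l^m(h),      N_l = 1 / (4 pi),

the canonical rotation-invariant inner product per harmonic order.
With the orthonormal basis and N_l = 1/(4 pi), sums of S_l are literal
sphere-surface-averaged moments:

    mean(g)   = c_0^0 / sqrt(4 pi)          (spherical mean, l = 0)
    var(g)    = sum_{l >= 2} S_l(g, g)      (anisotropic power)
    cov(g, h) = sum_{l >= 2} S_l(g, h)
    R^2(g, h) = cov^2 / (var(g) var(h))     (squared Pearson correlation)

R^2 is invariant under affine maps g -> a + b g and under common
rotations; voxels with zero variance are undefined (NaN) and excluded
from summary statistics.  The ensemble anisotropic power quotient

    Q = var(mean_i g_i) / mean_i var(g_i)

is 1 iff the anisotropic parts of all ensemble members coincide and
lies in [0, 1] otherwise (Cauchy-Schwarz).

All functions accept coefficient arrays with arbitrary leading batch
axes (..., M), so voxel maps are computed in one call.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import NamedTuple, Optional

import numpy as np

from .basis import (
    BasisConvention,
    _ell_max_from_n_coeffs,
    driscoll_healy_grid,
    evaluate_basis,
    expand_samples,
)

__all__ = [
    "cross_spectrum",
    "moments",
    "relative_anisotropy",
    "r_squared",
    "ensemble_q",
    "main_orientation",
    "expand_squared",
    "InvariantMaps",
    "compute_invariant_maps",
    "tukey_summary",
]

N_ELL = 1.0 / (4.0 * np.pi)


def _conv(coeffs: np.ndarray) -> BasisConvention:
    return BasisConvention(_ell_max_from_n_coeffs(np.asarray(coeffs).shape[-1]))


def cross_spectrum(g: np.ndarray, h: np.ndarray) -> np.ndarray:
    """S_l(g, h) for each even order; last axis runs over l = 0, 2, ...

    sum_l S_l equals the sphere-surface average of g * h.
    """
    g = np.asarray(g, dtype=float)
    h = np.asarray(h, dtype=float)
    if g.shape[-1] != h.shape[-1]:
        raise ValueError("g and h use different basis conventions")
    conv = _conv(g)
    out = np.empty(g.shape[:-1] + (conv.ell_max // 2 + 1,))
    for l, sl in conv.order_slices().items():
        out[..., l // 2] = N_ELL * np.sum(g[..., sl] * h[..., sl], axis=-1)
    return out


def moments(g: np.ndarray, h: Optional[np.ndarray] = None):
    """(spherical mean of g, var(g), cov(g, h)); cov(g, g) if h is None."""
    g = np.asarray(g, dtype=float)
    mean = g[..., 0] / np.sqrt(4.0 * np.pi)
    var = cross_spectrum(g, g)[..., 1:].sum(axis=-1)
    cov = var if h is None else cross_spectrum(g, h)[..., 1:].sum(axis=-1)
    return mean, var, cov


def relative_anisotropy(g: np.ndarray) -> np.ndarray:
    """sigma(g) / mean(g); NaN where the spherical mean is not positive.

    Normalizing the standard deviation by the mean (rather than the rms)
    keeps the measure unbounded, which preserves contrast for highly
    anisotropic maps; it is invariant under g -> k g for k > 0.
    """
    mean, var, _ = moments(g)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(mean > 0, np.sqrt(np.maximum(var, 0.0)) / mean, np.nan)
    return out


def r_squared(g: np.ndarray, h: np.ndarray) -> np.ndarray:
    """Squared Pearson correlation of two spherical functions, in [0, 1]."""
    _, var_g, _ = moments(g)
    _, var_h, _ = moments(h)
    _, _, cov = moments(g, np.asarray(h, dtype=float))
    denom = var_g * var_h
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(denom > 0, cov * cov / denom, np.nan)
    return np.clip(out, 0.0, 1.0, where=np.isfinite(out), out=np.asarray(out))


def ensemble_q(volumes) -> np.ndarray:
    """Anisotropic power quotient Q of an ensemble of coefficient fields.

    Q = var(ensemble-mean function) / ensemble-mean of var(g_i), per
    voxel.  Q = 1 when all members' anisotropic parts are identical,
    Q in [0, 1) when they differ; NaN where every member is isotropic.
    """
    from .projector import CoefficientVolume

    stack = np.stack(
        [v.values if isinstance(v, CoefficientVolume) else np.asarray(v, float) for v in volumes]
    )
    _, var_each, _ = moments(stack)
    _, var_mean, _ = moments(stack.mean(axis=0))
    denom = var_each.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        q = np.where(denom > 0, var_mean / denom, np.nan)
    return q


@lru_cache(maxsize=1)
def _rank2_tensor_map():
    # Linear map from the five l=2 coefficients to the symmetric
    # traceless second-moment tensor (1/4pi) * Int g(n) (n n^T - I/3) dOmega,
    # computed once by exact quadrature.
    from .basis import quadrature_grid

    conv = BasisConvention(2)
    dirs, wts = quadrature_grid(3)
    basis = evaluate_basis(dirs, conv)[:, 1:]  # drop l=0 (traceless part only)
    outer = dirs[:, :, None] * dirs[:, None, :] - np.eye(3) / 3.0
    return np.einsum("q,qm,qij->mij", wts, basis, outer) * N_ELL


class Orientation(NamedTuple):
    vector: np.ndarray
    eigenvalues: np.ndarray
    degenerate: bool


def main_orientation(g: np.ndarray) -> Orientation:
    """Fiber-like orientation axis of the l = 2 component.

    The five l = 2 coefficients map linearly to a symmetric traceless
    rank-2 tensor; the returned axis is the eigenvector of the distinct
    (extremal) eigenvalue - the axis about which the l = 2 part is
    closest to zonal.  The sign is fixed to the positive-z hemisphere
    (ties: positive x, then positive y).  Degenerate spectra are
    flagged; any vector of the degenerate subspace is returned.
    """
    g = np.asarray(g, dtype=float)
    conv = _conv(g)
    if conv.ell_max < 2:
        raise ValueError("orientation requires an l = 2 component")
    c2 = g[conv.order_slices()[2]]
    if not np.any(c2):
        raise ValueError("orientation undefined: l = 2 component is zero")
    tensor = np.einsum("m,mij->ij", c2, _rank2_tensor_map())
    evals, evecs = np.linalg.eigh(tensor)  # ascending
    gap_lo = evals[1] - evals[0]
    gap_hi = evals[2] - evals[1]
    scale = max(abs(evals[0]), abs(evals[2]), 1e-300)
    degenerate = abs(gap_lo - gap_hi) < 1e-9 * scale
    idx = 0 if gap_lo >= gap_hi else 2
    v = evecs[:, idx]
    # hemisphere sign convention
    for comp in (2, 0, 1):
        if abs(v[comp]) > 1e-12:
            if v[comp] < 0:
                v = -v
            break
    return Orientation(v, evals, degenerate)


def expand_squared(coefficients: np.ndarray, ell_max_out: int) -> np.ndarray:
    """Expand the square of a band-limited function in the plain basis.

    Squaring a band-ell_max_in polynomial yields a polynomial of band
    2 * ell_max_in; it is sampled on a Driscoll-Healy grid dense enough
    for the product with the analysis basis and re-expanded exactly.
    Used to bring squared-representation (ZH-style) reconstructions into
    the common linear representation for ensemble averaging.
    """
    coefficients = np.asarray(coefficients, dtype=float)
    ell_max_in = _ell_max_from_n_coeffs(coefficients.shape[-1])
    if ell_max_out < 2 * ell_max_in:
        raise ValueError(
            f"ell_max_out must be >= {2 * ell_max_in} to represent the square exactly"
        )
    conv_in = BasisConvention(ell_max_in)
    conv_out = BasisConvention(ell_max_out)
    # integrand degree: 2*ell_max_in (square) + ell_max_out (basis)
    bandwidth = (2 * ell_max_in + ell_max_out) // 2 + 1
    dirs, wts = driscoll_healy_grid(bandwidth)
    samples = coefficients @ evaluate_basis(dirs, conv_in).T
    return expand_samples(samples * samples, dirs, wts, conv_out)


# --- voxel maps and reporting --------------------------------------------

@dataclass
class InvariantMaps:
    """Voxel-wise rotation-invariant summaries of a coefficient field."""

    mean: np.ndarray
    power: np.ndarray
    rel_aniso: np.ndarray
    orientation: Optional[np.ndarray] = None
    r2: Optional[np.ndarray] = None
    q: Optional[np.ndarray] = None


def compute_invariant_maps(
    volume, reference=None, ensemble=None, with_orientation: bool = True
) -> InvariantMaps:
    """All per-voxel invariants of a (possibly reconstructed) field.

    ``reference`` (a ground-truth field with the same voxel grid, any
    band limit) adds the R^2 map; R^2 uses the common band limit of the
    two fields' conventions so the comparison is well defined.
    ``ensemble`` (list of per-run fields) adds the Q map.
    """
    from .projector import CoefficientVolume

    values = volume.values if isinstance(volume, CoefficientVolume) else np.asarray(volume)
    mean, var, _ = moments(values)
    maps = InvariantMaps(
        mean=mean, power=var, rel_aniso=relative_anisotropy(values)
    )
    if with_orientation and values.shape[-1] >= 6:
        conv = _conv(values)
        c2 = values[..., conv.order_slices()[2]]
        tensors = np.einsum("...m,mij->...ij", c2, _rank2_tensor_map())
        evals, evecs = np.linalg.eigh(tensors)
        pick = np.where(
            evals[..., 1] - evals[..., 0] >= evals[..., 2] - evals[..., 1], 0, 2
        )
        vecs = np.take_along_axis(
            evecs, pick[..., None, None].repeat(3, axis=-2), axis=-1
        )[..., 0]
        sign = np.where(vecs[..., 2] < 0, -1.0, 1.0)
        maps.orientation = vecs * sign[..., None]
    if reference is not None:
        from .model import _pad_to_common_band

        ref = reference.values if isinstance(reference, CoefficientVolume) else np.asarray(reference)
        a, b = _pad_to_common_band(values, ref)
        maps.r2 = r_squared(a, b)
    if ensemble is not None:
        maps.q = ensemble_q(ensemble)
    return maps


def tukey_summary(values: np.ndarray, whisker_factor: float = 1.25) -> dict:
    """Box-plot statistics: quartiles and whiskers at Q1/Q3 -/+ 1.25 IQR.

    Whiskers span the smallest and largest observation inside the
    factor-scaled interquartile fence; NaNs (undefined voxels) are
    excluded.
    """
    v = np.asarray(values, dtype=float).ravel()
    v = v[np.isfinite(v)]
    if v.size == 0:
        return {k: np.nan for k in ("q1", "median", "q3", "lo", "hi", "n")}
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - whisker_factor * iqr, q3 + whisker_factor * iqr
    inside = v[(v >= lo_fence) & (v <= hi_fence)]
    return {
        "q1": float(q1),
        "median": float(med),
        "q3": float(q3),
        "lo": float(inside.min()),
        "hi": float(inside.max()),
        "n": int(v.size),
    }
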