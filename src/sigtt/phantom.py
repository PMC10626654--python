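"""Synthetic textured samples and their simulated measurements.

The generator emulates volumes whose per-voxel reciprocal-space maps
vary smoothly around a few "source" functions:

1. source points are placed by farthest-point (maximin) sampling under
   the interior (through-the-mask) distance;
2. each source carries a band-limited spherical function whose spectral
   power follows a power-law decay over even orders;
3. interior distances from every source are computed by Dijkstra's
   algorithm on the 26-connected voxel graph;
4. every other voxel receives a function whose per-order power equals
   the distance-weighted (Gaussian-kernel) average of the source powers
   and whose correlation with the nearest source decays with interior
   distance like a Gaussian with the source's correlation length as its
   standard deviation; a smooth random field supplies the decorrelated
   remainder;
5. the isotropic component is raised until a dense sampling of every
   function is non-negative.

Three symmetry classes mirror the canonical test samples: ``zonal``
(approximately zonally symmetric maps, band limit 12), ``rank2``
(symmetric rank-2 tensors only, band limit 2) and ``high_order`` (band
limit 8 with the l = 2 power damped to match l = 4).  With the default
8 azimuthal bins only band limits up to 6 are exactly recoverable, so
zonal and high_order phantoms are deliberately *not* exactly
recoverable by the reconstruction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra as _dijkstra

from .basis import BasisConvention, evaluate_basis
from .forward_model import AzimuthalBinning, BinnedMeasurement, predict
from .geometry import ProjectionGeometry
from .projector import CoefficientVolume

logger = logging.getLogger(__name__)

__all__ = [
    "PhantomSpec",
    "farthest_point_sources",
    "interior_distance",
    "synthesize_field",
    "enforce_nonnegativity",
    "simulate_measurements",
    "canonical_spec",
    "ellipsoid_mask",
]

_CLASS_ELL_MAX = {"zonal": 12, "rank2": 2, "high_order": 8}


def ellipsoid_mask(shape) -> np.ndarray:
    """Solid ellipsoid inscribed in the volume box."""
    grids = np.meshgrid(
        *[(np.arange(n) - (n - 1) / 2) / (n / 2) for n in shape], indexing="ij"
    )
    return sum(g * g for g in grids) <= 1.0


@dataclass
class PhantomSpec:
    """Everything needed to generate one synthetic sample.

    ``power_decay`` is the exponent of the per-order spectral power law
    P(l) ~ (1 + l)^(-power_decay).  ``correlation_lengths`` (voxel
    units, one per source) default to a quarter of the mask diameter.
    ``zonal_weight_decay`` gives w(l) = 1/(2l+1)^zonal_weight_decay for
    the l-weighted delta that zonal-class sources correlate with.
    """

    volume_shape: tuple
    symmetry_class: str = "rank2"
    n_sources: int = 2
    ell_max: Optional[int] = None
    power_decay: float = 1.5
    correlation_lengths: Optional[np.ndarray] = None
    support_mask: Optional[np.ndarray] = None
    seed: int = 0
    zonal_weight_decay: float = 1.0

    def __post_init__(self):
        if self.symmetry_class not in _CLASS_ELL_MAX:
            raise ValueError(
                f"symmetry_class must be one of {sorted(_CLASS_ELL_MAX)}"
            )
        if self.ell_max is None:
            self.ell_max = _CLASS_ELL_MAX[self.symmetry_class]
        if self.n_sources < 1:
            raise ValueError("n_sources must be >= 1")
        self.volume_shape = tuple(int(n) for n in self.volume_shape)
        if self.support_mask is None:
            self.support_mask = ellipsoid_mask(self.volume_shape)
        self.support_mask = np.asarray(self.support_mask, dtype=bool)
        if self.support_mask.shape != self.volume_shape:
            raise ValueError("support_mask shape must match volume_shape")
        if self.correlation_lengths is None:
            diameter = float(np.linalg.norm(self.volume_shape))
            self.correlation_lengths = np.full(self.n_sources, diameter / 4.0)
        self.correlation_lengths = np.atleast_1d(
            np.asarray(self.correlation_lengths, dtype=float)
        )
        if self.correlation_lengths.size == 1:
            self.correlation_lengths = np.repeat(
                self.correlation_lengths, self.n_sources
            )
        if np.any(self.correlation_lengths <= 0):
            raise ValueError("correlation lengths must be positive")

    @property
    def convention(self) -> BasisConvention:
        return BasisConvention(self.ell_max)

    def source_powers(self, rng: np.random.Generator) -> np.ndarray:
        """(n_sources, n_orders) spectral powers with power-law decay."""
        ells = np.arange(0, self.ell_max + 1, 2)
        base = (1.0 + ells) ** (-self.power_decay)
        amp = rng.uniform(0.5, 1.5, size=self.n_sources)
        powers = amp[:, None] * base[None, :]
        if self.symmetry_class == "high_order" and self.ell_max >= 4:
            powers[:, 1] = powers[:, 2]  # damp l=2 to match l=4
        return powers


def canonical_spec(kind: str, volume_shape=None, seed: int = 0) -> PhantomSpec:
    """Analogues of the canonical samples: 'M' (zonal, 50^3 voxels,
    4 sources), 'T' (rank-2, 50^3, 2 sources), 'mammoth' (high-order,
    60x60x80, 5 sources).  Pass ``volume_shape`` for scaled-down
    variants (tests default to 16^3)."""
    presets = {
        "M": ("zonal", (50, 50, 50), 4),
        "T": ("rank2", (50, 50, 50), 2),
        "mammoth": ("high_order", (60, 60, 80), 5),
    }
    if kind not in presets:
        raise ValueError(f"kind must be one of {sorted(presets)}")
    cls, shape, n_src = presets[kind]
    return PhantomSpec(
        volume_shape=volume_shape or shape,
        symmetry_class=cls,
        n_sources=n_src,
        seed=seed,
    )


# --- geometry of the support ---------------------------------------------

def _mask_graph(mask: np.ndarray):
    """Sparse 26-connected adjacency of mask voxels, Euclidean weights."""
    mask = np.asarray(mask, dtype=bool)
    n = int(mask.sum())
    if n == 0:
        raise ValueError("support mask is empty")
    idx = -np.ones(mask.shape, dtype=np.int64)
    idx[mask] = np.arange(n)
    coords = np.argwhere(mask)
    rows, cols, wts = [], [], []
    offsets = [
        (dx, dy, dz)
        for dx in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dz in (-1, 0, 1)
        if (dx, dy, dz) > (0, 0, 0)  # each unordered pair once
    ]
    for off in offsets:
        w = float(np.linalg.norm(off))
        nbr = coords + np.asarray(off)
        ok = np.all((nbr >= 0) & (nbr < np.asarray(mask.shape)), axis=1)
        nbr = nbr[ok]
        ok2 = mask[nbr[:, 0], nbr[:, 1], nbr[:, 2]]
        a = idx[tuple(coords[ok][ok2].T)]
        b = idx[tuple(nbr[ok2].T)]
        rows.append(a)
        cols.append(b)
        wts.append(np.full(a.size, w))
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    wts = np.concatenate(wts)
    graph = coo_matrix((wts, (rows, cols)), shape=(n, n)).tocsr()
    return graph, idx


def interior_distance(mask: np.ndarray, sources) -> np.ndarray:
    """Shortest-path distance through the mask from each source voxel.

    Returns (n_sources,) + mask.shape volumes; np.inf outside the mask
    and in mask components unreachable from the source (flagged in the
    log).  Distances use Euclidean edge weights on the 26-connected
    voxel lattice, so they exceed the straight-line distance by at most
    a small lattice factor on convex masks.
    """
    mask = np.asarray(mask, dtype=bool)
    graph, idx = _mask_graph(mask)
    sources = [tuple(int(c) for c in s) for s in np.atleast_2d(sources)]
    for s in sources:
        if not mask[s]:
            raise ValueError(f"source {s} lies outside the support mask")
    node_ids = [int(idx[s]) for s in sources]
    dist = _dijkstra(graph, directed=False, indices=node_ids)
    out = np.full((len(sources),) + mask.shape, np.inf)
    for i in range(len(sources)):
        out[i][mask] = dist[i]
    if np.isinf(dist).any():
        logger.warning(
            "support mask has components unreachable from some sources"
        )
    return out


def farthest_point_sources(mask: np.ndarray, n_sources: int, seed: int = 0):
    """Greedy maximin (farthest-point) placement under interior distance.

    The seeded start voxel only initializes the greedy sweep: n + 1
    points are selected and the arbitrary start is dropped, so e.g. the
    two sources on a thin rod are its end voxels.  Deterministic for a
    fixed seed (ties broken by voxel order).
    """
    mask = np.asarray(mask, dtype=bool)
    coords = np.argwhere(mask)
    if coords.shape[0] < n_sources:
        raise ValueError("mask has fewer voxels than requested sources")
    rng = np.random.default_rng(seed)
    start = tuple(coords[rng.integers(coords.shape[0])])
    chosen = []
    # distances to the throwaway start seed the sweep but are not kept
    min_dist = interior_distance(mask, [start])[0][mask]
    for i in range(n_sources):
        nxt = tuple(coords[int(np.argmax(min_dist))])
        chosen.append(nxt)
        d = interior_distance(mask, [nxt])[0][mask]
        min_dist = d if i == 0 else np.minimum(min_dist, d)
    return [tuple(int(c) for c in p) for p in chosen]


# --- field synthesis ------------------------------------------------------

def _unit_block(rng, size):
    v = rng.normal(size=size)
    return v / np.linalg.norm(v)


def _smooth_noise(rng, shape, n_channels, sigma):
    noise = rng.normal(size=shape + (n_channels,))
    for c in range(n_channels):
        noise[..., c] = gaussian_filter(noise[..., c], sigma=sigma, mode="nearest")
    return noise


def synthesize_field(spec: PhantomSpec) -> CoefficientVolume:
    """Generate the ground-truth coefficient volume for a phantom spec."""
    rng = np.random.default_rng(spec.seed)
    conv = spec.convention
    mask = spec.support_mask
    sources = farthest_point_sources(mask, spec.n_sources, spec.seed)
    dists = interior_distance(mask, sources)  # (S, nx, ny, nz)
    powers = spec.source_powers(rng)  # (S, n_orders)
    L = spec.correlation_lengths
    kernels = np.exp(-(dists**2) / (2.0 * L[:, None, None, None] ** 2))
    kernels[~np.isfinite(dists)] = 0.0
    ksum = kernels.sum(axis=0)
    ksum = np.where(ksum > 1e-12, ksum, 1.0)
    # per-voxel, per-order target power: distance-weighted source average
    target_power = (
        np.einsum("sxyz,so->xyzo", kernels, powers) / ksum[..., None]
    )
    rho = np.clip(kernels.max(axis=0), 0.0, 0.999)  # corr with nearest source

    values = np.zeros(spec.volume_shape + (conv.n_coeffs,))
    # isotropic component straight from the l=0 power: S_0 = c00^2/(4pi)
    values[..., 0] = np.sqrt(4.0 * np.pi * np.maximum(target_power[..., 0], 0.0))

    if spec.symmetry_class == "zonal":
        _fill_zonal(values, spec, conv, rng, kernels, target_power, rho)
    else:
        _fill_generic(values, spec, conv, rng, kernels, target_power, rho)

    values[~mask] = 0.0
    vol = CoefficientVolume(values, conv)
    return enforce_nonnegativity(vol)


def _fill_generic(values, spec, conv, rng, kernels, target_power, rho):
    # mixture of unit source vectors plus smooth orthogonalized noise,
    # per order block, scaled to the target power
    slices = conv.order_slices()
    sigma = float(np.mean(spec.correlation_lengths)) / 2.0
    for l, sl in slices.items():
        if l == 0:
            continue
        width = 2 * l + 1
        src_vecs = np.stack(
            [_unit_block(rng, width) for _ in range(spec.n_sources)]
        )  # (S, width)
        u = np.einsum("sxyz,sw->xyzw", kernels, src_vecs)
        norm = np.linalg.norm(u, axis=-1, keepdims=True)
        u = np.where(norm > 1e-12, u / np.where(norm > 0, norm, 1.0), 0.0)
        xi = _smooth_noise(rng, spec.volume_shape, width, sigma)
        xi -= np.sum(xi * u, axis=-1, keepdims=True) * u  # decorrelate
        norm_xi = np.linalg.norm(xi, axis=-1, keepdims=True)
        xi = np.where(norm_xi > 1e-12, xi / np.where(norm_xi > 0, norm_xi, 1.0), 0.0)
        # block power = 4pi * S_l target
        amp = np.sqrt(4.0 * np.pi * np.maximum(target_power[..., l // 2], 0.0))
        mix = rho[..., None] * u + np.sqrt(1.0 - rho[..., None] ** 2) * xi
        values[..., sl] = amp[..., None] * mix


def _fill_zonal(values, spec, conv, rng, kernels, target_power, rho):
    # exactly zonal function about a smoothly varying axis field; each
    # source correlates with the l-weighted spherical delta about its axis
    axes = rng.normal(size=(spec.n_sources, 3))
    axes /= np.linalg.norm(axes, axis=1, keepdims=True)
    # orientation tensor field: source axes mixed by kernel weight plus
    # a smooth perturbation where no source dominates
    tensor = np.einsum("sxyz,si,sj->xyzij", kernels, axes, axes)
    wfield = _smooth_noise(rng, spec.volume_shape, 3, np.mean(spec.correlation_lengths) / 2.0)
    wnorm = np.linalg.norm(wfield, axis=-1, keepdims=True)
    wfield = wfield / np.where(wnorm > 1e-12, wnorm, 1.0)
    tensor += (
        0.5
        * (1.0 - rho[..., None, None])
        * np.einsum("...i,...j->...ij", wfield, wfield)
    )
    evals, evecs = np.linalg.eigh(tensor)
    axis_field = evecs[..., -1]  # principal axis per voxel
    flat_axes = axis_field.reshape(-1, 3)
    norms = np.linalg.norm(flat_axes, axis=1, keepdims=True)
    flat_axes = flat_axes / np.where(norms > 1e-12, norms, 1.0)
    basis_rows = evaluate_basis(flat_axes, conv)  # (n_vox, M)
    slices = conv.order_slices()
    for l, sl in slices.items():
        if l == 0:
            continue
        # unit zonal block about the axis: Y_l(axis) * sqrt(4pi/(2l+1)),
        # sign alternating so the function peaks on the equatorial ring
        sign = (-1.0) ** (l // 2)
        block = basis_rows[:, sl].reshape(spec.volume_shape + (2 * l + 1,))
        amp = np.sqrt(4.0 * np.pi * np.maximum(target_power[..., l // 2], 0.0))
        values[..., sl] = (
            sign
            * amp[..., None]
            * np.sqrt(4.0 * np.pi / (2 * l + 1))
            * block
        )


def _fibonacci_sphere(n: int) -> np.ndarray:
    i = np.arange(n) + 0.5
    z = 1.0 - 2.0 * i / n
    phi = np.pi * (1.0 + np.sqrt(5.0)) * i
    r = np.sqrt(np.maximum(1.0 - z * z, 0.0))
    return np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=-1)


def enforce_nonnegativity(
    volume: CoefficientVolume, sampling_grid: Optional[np.ndarray] = None
) -> CoefficientVolume:
    """Raise the isotropic component until sampled functions are >= 0.

    Non-negativity cannot be enforced exactly for spherical polynomials;
    a dense sampling (default: ~quasi-uniform Fibonacci grid scaled to
    the band limit) detects negative values and only the l = 0
    coefficient grows, by -min * sqrt(4 pi).  Idempotent up to grid
    resolution.
    """
    conv = volume.convention
    if sampling_grid is None:
        sampling_grid = _fibonacci_sphere(max(1000, 8 * (conv.ell_max + 1) ** 2))
    basis = evaluate_basis(sampling_grid, conv)  # (G, M)
    flat = volume.values.reshape(-1, conv.n_coeffs)
    out = flat.copy()
    chunk = 65536
    for i in range(0, flat.shape[0], chunk):
        sampled_min = (flat[i : i + chunk] @ basis.T).min(axis=1)
        lift = np.maximum(-sampled_min, 0.0)
        # adding a constant d to the function raises c00 by d * sqrt(4 pi)
        out[i : i + chunk, 0] += lift * np.sqrt(4.0 * np.pi)
    return CoefficientVolume(
        out.reshape(volume.values.shape), conv, volume.voxel_size
    )


def simulate_measurements(
    volume: CoefficientVolume,
    geometry: ProjectionGeometry,
    binning: AzimuthalBinning = AzimuthalBinning(),
    snr: float = np.inf,
    seed: int = 0,
    noise: str = "gaussian",
) -> BinnedMeasurement:
    """Forward-project a phantom and add detector noise at a target SNR.

    SNR is defined as (mean nonzero noiseless signal) / (noise standard
    deviation).  ``noise='gaussian'`` adds i.i.d. Gaussian noise with
    that standard deviation, clipped at zero (clip count logged and
    stored on the result as ``n_clipped``); ``noise='poisson'`` scales
    intensities so the Poisson shot noise matches the requested SNR at
    the mean.  ``snr=inf`` returns the noiseless model data.
    """
    if not (snr > 0):
        raise ValueError("snr must be positive (np.inf for noiseless)")
    clean = predict(volume, geometry, binning)
    if not np.isfinite(snr):
        clean.n_clipped = 0
        return clean
    rng = np.random.default_rng(seed)
    data = clean.data
    mean_signal = float(data[data > 0].mean()) if np.any(data > 0) else 0.0
    if noise == "gaussian":
        sigma = mean_signal / snr
        noisy = data + rng.normal(0.0, sigma, size=data.shape)
        n_clipped = int((noisy < 0).sum())
        noisy = np.clip(noisy, 0.0, None)
    elif noise == "poisson":
        scale = snr**2 / max(mean_signal, 1e-300)
        noisy = rng.poisson(np.clip(data, 0.0, None) * scale) / scale
        n_clipped = 0
    else:
        raise ValueError("noise must be 'gaussian' or 'poisson'")
    if n_clipped:
        logger.info("clipped %d negative intensities to zero", n_clipped)
    out = BinnedMeasurement(noisy, binning)
    out.n_clipped = n_clipped
    return out
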