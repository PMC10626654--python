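"""Model/Results interface to the reconstruction pipeline.

`SAXSTensorTomography` bundles the measured data, acquisition geometry
and solver settings into a single fit-able object, in the style of
statistical modelling packages: ``model.fit()`` returns a
:class:`TensorTomographyResults` carrying the estimated coefficient
volume, the convergence record, invariant diagnostics and a printable
``summary()``.  ``fit_ensemble()`` repeats the fit with randomized
initial conditions and exposes the ensemble consistency map Q.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Optional

import numpy as np

from .forward_model import AzimuthalBinning, BinnedMeasurement, loss_and_gradient
from .geometry import ProjectionGeometry
from .invariants import (
    compute_invariant_maps,
    ensemble_q,
    r_squared,
    tukey_summary,
)
from .projector import CoefficientVolume
from .solver import (
    ConvergenceRecord,
    ReconstructionConfig,
    default_lambda,
    ensemble_reconstruct,
    reconstruct,
)

__all__ = ["SAXSTensorTomography", "TensorTomographyResults"]


def _pad_to_common_band(a: np.ndarray, b: np.ndarray):
    """Zero-pad the narrower coefficient field to the wider band limit.

    A band-limited field is exactly representable at any higher band
    limit with zero high-order coefficients; truncating the wider field
    instead would discard reference variance and inflate R^2.
    """
    m = max(a.shape[-1], b.shape[-1])

    def pad(x):
        if x.shape[-1] == m:
            return x
        out = np.zeros(x.shape[:-1] + (m,))
        out[..., : x.shape[-1]] = x
        return out

    return pad(a), pad(b)


class SAXSTensorTomography:
    """Regularized least-squares tensor-tomography model.

    Parameters
    ----------
    data
        Azimuthally binned measurements, one raster per projection.
    geometry
        Projection angles, raster grid and volume metadata.
    ell_max, lam, mode, **config_kwargs
        Forwarded to :class:`ReconstructionConfig`; ``lam=None`` uses
        the data-scaled heuristic.
    """

    def __init__(
        self,
        data: BinnedMeasurement,
        geometry: ProjectionGeometry,
        ell_max: int = 6,
        lam: Optional[float] = None,
        mode: str = "full",
        **config_kwargs,
    ):
        self.data = data
        self.geometry = geometry
        self.config = ReconstructionConfig(
            ell_max=ell_max, lam=lam, mode=mode, **config_kwargs
        )

    @classmethod
    def from_container(cls, path, **kwargs) -> "SAXSTensorTomography":
        from .io import read_container

        c = read_container(path)
        return cls(c.data, c.geometry, **kwargs)

    @property
    def effective_lambda(self) -> float:
        if self.config.lam is not None:
            return self.config.lam
        return default_lambda(self.data, self.geometry)

    def loss(self, volume: CoefficientVolume) -> float:
        f, _ = loss_and_gradient(
            volume, self.data, self.geometry, self.effective_lambda
        )
        return f

    def fit(
        self, initial: Optional[CoefficientVolume] = None, **overrides
    ) -> "TensorTomographyResults":
        config = replace(self.config, **overrides) if overrides else self.config
        volume, record = reconstruct(self.data, self.geometry, config, initial)
        return TensorTomographyResults(self, volume, record, config)

    def fit_ensemble(
        self, n_runs: int = 10, seeds=None, **overrides
    ) -> "TensorTomographyResults":
        config = replace(self.config, **overrides) if overrides else self.config
        runs, average, records = ensemble_reconstruct(
            self.data, self.geometry, config, n_runs, seeds
        )
        result = TensorTomographyResults(self, average, records[0], config)
        result.ensemble_runs = runs
        result.ensemble_records = records
        return result


class TensorTomographyResults:
    """Fitted coefficient volume plus diagnostics."""

    def __init__(
        self,
        model: SAXSTensorTomography,
        volume: CoefficientVolume,
        record: ConvergenceRecord,
        config: ReconstructionConfig,
    ):
        self.model = model
        self.volume = volume
        self.record = record
        self.config = config
        self.ensemble_runs = None
        self.ensemble_records = None

    @property
    def loss_history(self) -> np.ndarray:
        return self.record.loss_history

    def invariant_maps(self, reference: Optional[CoefficientVolume] = None):
        return compute_invariant_maps(
            self.volume, reference=reference, ensemble=self.ensemble_runs
        )

    def r_squared_map(self, reference: CoefficientVolume) -> np.ndarray:
        a, b = _pad_to_common_band(self.volume.values, reference.values)
        return r_squared(a, b)

    def q_map(self) -> np.ndarray:
        if not self.ensemble_runs:
            raise ValueError("Q requires an ensemble fit (use fit_ensemble)")
        return ensemble_q(self.ensemble_runs)

    def save(self, path, ground_truth: Optional[CoefficientVolume] = None):
        from .io import DatasetContainer, config_to_yaml, write_container

        contents = DatasetContainer(
            geometry=self.model.geometry,
            data=self.model.data,
            ground_truth=ground_truth,
            reconstruction=self.volume,
            loss_history=self.record.loss_history,
            meta={"reconstruction_config": config_to_yaml(self.config)},
        )
        write_container(path, contents)

    def summary(self, reference: Optional[CoefficientVolume] = None) -> str:
        maps = self.invariant_maps(reference=reference)
        nonempty = maps.mean > 0
        lines = [
            "SAXS tensor tomography reconstruction",
            "=" * 53,
            f"volume shape        : {self.volume.shape}",
            f"band limit ell_max  : {self.config.ell_max} "
            f"({self.volume.convention.n_coeffs} coefficients/voxel)"
            + ("  [rank-2 restricted]" if self.config.mode == "rank2" else ""),
            f"projections         : {self.model.geometry.n_projections}",
            f"azimuthal bins      : {self.model.data.binning.n_bins}",
            f"lambda (smoothness) : {self.model.effective_lambda:.4g}",
            f"iterations          : {self.record.n_iterations}"
            f" (converged: {self.record.converged})",
            f"final loss          : {self.record.final_loss:.6g}",
            f"non-empty voxels    : {int(nonempty.sum())}",
        ]
        ra = tukey_summary(maps.rel_aniso[nonempty])
        lines.append(
            f"relative anisotropy : median {ra['median']:.3f} "
            f"(IQR {ra['q1']:.3f}-{ra['q3']:.3f})"
        )
        if maps.r2 is not None:
            r2 = tukey_summary(maps.r2[nonempty])
            lines.append(
                f"R^2 vs reference    : median {r2['median']:.3f} "
                f"(IQR {r2['q1']:.3f}-{r2['q3']:.3f})"
            )
        if maps.q is not None:
            q = tukey_summary(maps.q[nonempty])
            lines.append(f"ensemble Q          : median {q['median']:.4f}")
        return "\n".join(lines)
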