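"""HDF5 dataset containers and flat-binary exports.

No community standard exists for binned tensor-tomography data, so the
package defines a documented HDF5 layout that every pipeline stage
(simulate, reconstruct, analyze, ensemble) reads and writes:

    /                 attrs: format_version, package_version,
                      coordinate_convention, basis ordering/normalization
    /geometry         alphas, betas [rad]; attrs raster_shape,
                      volume_shape, voxel_size
    /binning          bin_centers; attrs bin_width, n_bins
    /data             intensities (P, n_j, n_k, N); optional mask
    /ground_truth     coefficients (nx, ny, nz, M); attrs ell_max, spec
    /reconstruction   coefficients, loss_history; attrs config, seed
    /analysis         mean, power, rel_aniso, orientation, r2, q

Arrays round-trip bit-exactly; groups the reader does not know are left
untouched when a container is updated in place.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Optional

import h5py
import numpy as np
import yaml

from . import __version__
from .basis import BasisConvention
from .forward_model import AzimuthalBinning, BinnedMeasurement
from .geometry import ProjectionGeometry
from .projector import CoefficientVolume

__all__ = ["DatasetContainer", "write_container", "read_container", "export_raw"]

FORMAT_VERSION = "1"
COORDINATE_CONVENTION = (
    "u=(cos a cos b, sin a cos b, sin b); e_j=(-sin a, cos a, 0); "
    "e_k = u x e_j; detector phi=0 along e_j; raster step = voxel size"
)


@dataclass
class DatasetContainer:
    """In-memory mirror of one container file."""

    geometry: Optional[ProjectionGeometry] = None
    data: Optional[BinnedMeasurement] = None
    ground_truth: Optional[CoefficientVolume] = None
    reconstruction: Optional[CoefficientVolume] = None
    loss_history: Optional[np.ndarray] = None
    analysis: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)


def _write_volume(group, volume: CoefficientVolume):
    group.create_dataset("coefficients", data=volume.values)
    group.attrs["ell_max"] = volume.convention.ell_max
    group.attrs["voxel_size"] = volume.voxel_size
    group.attrs["basis"] = json.dumps(volume.convention.describe())


def _read_volume(group) -> CoefficientVolume:
    return CoefficientVolume(
        group["coefficients"][()],
        BasisConvention(int(group.attrs["ell_max"])),
        float(group.attrs.get("voxel_size", 1.0)),
    )


def write_container(path, contents: DatasetContainer, mode: str = "w"):
    """Write (or update, with mode='a') a container file."""
    with h5py.File(path, mode) as f:
        f.attrs["format_version"] = FORMAT_VERSION
        f.attrs["package_version"] = __version__
        f.attrs["coordinate_convention"] = COORDINATE_CONVENTION
        for key, value in contents.meta.items():
            f.attrs[key] = value
        if contents.geometry is not None:
            g = _fresh_group(f, "geometry")
            g.create_dataset("alphas", data=contents.geometry.alphas)
            g.create_dataset("betas", data=contents.geometry.betas)
            g.attrs["raster_shape"] = contents.geometry.raster_shape
            g.attrs["volume_shape"] = contents.geometry.volume_shape
            g.attrs["voxel_size"] = contents.geometry.voxel_size
        if contents.data is not None:
            b = _fresh_group(f, "binning")
            b.create_dataset("bin_centers", data=contents.data.binning.bin_centers)
            b.attrs["bin_width"] = contents.data.binning.bin_width
            b.attrs["n_bins"] = contents.data.binning.n_bins
            d = _fresh_group(f, "data")
            d.create_dataset("intensities", data=contents.data.data)
            if contents.data.mask is not None:
                d.create_dataset("mask", data=contents.data.mask)
        if contents.ground_truth is not None:
            _write_volume(_fresh_group(f, "ground_truth"), contents.ground_truth)
        if contents.reconstruction is not None:
            r = _fresh_group(f, "reconstruction")
            _write_volume(r, contents.reconstruction)
            if contents.loss_history is not None:
                r.create_dataset("loss_history", data=contents.loss_history)
        if contents.analysis:
            a = _fresh_group(f, "analysis")
            for key, value in contents.analysis.items():
                if value is not None:
                    a.create_dataset(key, data=value)


def _fresh_group(f, name):
    if name in f:
        del f[name]
    return f.create_group(name)


def read_container(path, require=("geometry", "binning", "data")) -> DatasetContainer:
    """Read a container; missing required groups raise with the group named."""
    out = DatasetContainer()
    with h5py.File(path, "r") as f:
        version = str(f.attrs.get("format_version", ""))
        if version != FORMAT_VERSION:
            warnings.warn(
                f"container format version {version!r} differs from "
                f"{FORMAT_VERSION!r}; reading anyway",
                stacklevel=2,
            )
        for name in require:
            if name not in f:
                raise KeyError(f"container {path} is missing required group '{name}'")
        out.meta = {k: f.attrs[k] for k in f.attrs}
        if "geometry" in f:
            g = f["geometry"]
            out.geometry = ProjectionGeometry(
                g["alphas"][()],
                g["betas"][()],
                tuple(g.attrs["raster_shape"]),
                tuple(g.attrs["volume_shape"]),
                float(g.attrs["voxel_size"]),
            )
        if "data" in f:
            if "binning" not in f:
                raise KeyError(f"container {path} has 'data' but no 'binning' group")
            binning = AzimuthalBinning(int(f["binning"].attrs["n_bins"]))
            d = f["data"]
            mask = d["mask"][()] if "mask" in d else None
            out.data = BinnedMeasurement(d["intensities"][()], binning, mask)
        if "ground_truth" in f:
            out.ground_truth = _read_volume(f["ground_truth"])
        if "reconstruction" in f:
            out.reconstruction = _read_volume(f["reconstruction"])
            if "loss_history" in f["reconstruction"]:
                out.loss_history = f["reconstruction"]["loss_history"][()]
        if "analysis" in f:
            out.analysis = {k: f["analysis"][k][()] for k in f["analysis"]}
    return out


def export_raw(array: np.ndarray, path):
    """Flat little-endian float32 binary plus a JSON sidecar.

    For external visualization tools that read raw volumes; the sidecar
    records shape, dtype and C order.
    """
    arr = np.ascontiguousarray(array, dtype="<f4")
    arr.tofile(path)
    sidecar = {
        "shape": list(arr.shape),
        "dtype": "<f4",
        "order": "C",
        "coordinate_convention": COORDINATE_CONVENTION,
    }
    with open(str(path) + ".json", "w") as fh:
        json.dump(sidecar, fh, indent=1)


def config_to_yaml(obj) -> str:
    """Serialize a dataclass-like config for container attributes."""
    from dataclasses import asdict, is_dataclass

    if is_dataclass(obj):
        d = asdict(obj)
        d = {
            k: (v.tolist() if isinstance(v, np.ndarray) else v)
            for k, v in d.items()
            if not isinstance(v, np.ndarray) or v.size < 1000
        }
        return yaml.safe_dump(d)
    return yaml.safe_dump(obj)
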