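"""HDF5 container and NIfTI import/export for gridded pipeline objects.

Every object is stored in a single HDF5 file with a ``kind`` attribute and
mandatory spatial metadata (``voxel_size_mm``, ``origin_mm``, and
``frequency_Hz`` where applicable); loading refuses files with missing
metadata rather than guessing defaults.  Complex fields are stored as
paired real/imaginary datasets.  Label maps and scalar volumes can also be
exchanged as NIfTI, with the voxel size carried in the affine.
"""

from __future__ import annotations

import json

import h5py
import nibabel as nib
import numpy as np

from .grids import (ComplexPressurePlane, ComplexPressureVolume, LabelMap,
                    PowerDepositionVolume, TemperatureSeries, VoxelModel)

__all__ = ["save_h5", "load_h5", "labelmap_to_nifti", "labelmap_from_nifti",
           "volume_to_nifti"]


def _require(attrs, *names):
    missing = [n for n in names if n not in attrs]
    if missing:
        raise KeyError(f"missing required metadata {missing}; refusing to "
                       "load without spatial information")
    return [attrs[n] for n in names]


def _store_complex(g, name, arr):
    g.create_dataset(f"{name}_real", data=np.ascontiguousarray(arr.real))
    g.create_dataset(f"{name}_imag", data=np.ascontiguousarray(arr.imag))


def _read_complex(g, name):
    return np.asarray(g[f"{name}_real"]) + 1j * np.asarray(g[f"{name}_imag"])


def save_h5(obj, path) -> None:
    """Write any pipeline grid object to an HDF5 container."""
    with h5py.File(path, "w") as f:
        if isinstance(obj, LabelMap):
            f.attrs["kind"] = "label_map"
            f.create_dataset("labels", data=obj.labels)
            f.attrs["voxel_size_mm"] = obj.voxel_size
            f.attrs["origin_mm"] = obj.origin
            f.attrs["label_key"] = json.dumps(
                {str(k): v for k, v in obj.label_key.items()})
        elif isinstance(obj, VoxelModel):
            f.attrs["kind"] = "voxel_model"
            for name in ("speed", "attenuation", "density"):
                f.create_dataset(name, data=getattr(obj, name))
            f.attrs["voxel_size_mm"] = obj.voxel_size
            f.attrs["origin_mm"] = obj.origin
            f.attrs["frequency_Hz"] = obj.frequency
        elif isinstance(obj, ComplexPressurePlane):
            f.attrs["kind"] = "pressure_plane"
            _store_complex(f, "p", obj.values)
            f.attrs["pixel_size_mm"] = obj.pixel_size
            f.attrs["plane_z_mm"] = obj.plane_z
            f.attrs["frequency_Hz"] = obj.frequency
            f.attrs["origin_xy_mm"] = obj.origin_xy
        elif isinstance(obj, ComplexPressureVolume):
            f.attrs["kind"] = "pressure_volume"
            _store_complex(f, "p", obj.values)
            f.attrs["voxel_size_mm"] = obj.voxel_size
            f.attrs["origin_mm"] = obj.origin
            f.attrs["frequency_Hz"] = obj.frequency
        elif isinstance(obj, PowerDepositionVolume):
            f.attrs["kind"] = "power_deposition"
            f.create_dataset("Q", data=obj.Q)
            f.attrs["voxel_size_mm"] = obj.voxel_size
            f.attrs["origin_mm"] = obj.origin
        elif isinstance(obj, TemperatureSeries):
            f.attrs["kind"] = "temperature_series"
            f.create_dataset("times", data=obj.times)
            f.create_dataset("fields", data=obj.fields)
            f.attrs["voxel_size_mm"] = obj.voxel_size
            f.attrs["origin_mm"] = obj.origin
        else:
            raise TypeError(f"cannot store object of type {type(obj)}")


def load_h5(path):
    """Load a pipeline grid object from an HDF5 container."""
    with h5py.File(path, "r") as f:
        kind = f.attrs.get("kind")
        if kind is None:
            raise KeyError("file has no 'kind' attribute; not a fusim "
                           "container")
        if kind == "label_map":
            vs, origin = _require(f.attrs, "voxel_size_mm", "origin_mm")
            key = {int(k): v for k, v in
                   json.loads(f.attrs["label_key"]).items()}
            return LabelMap(np.asarray(f["labels"]), float(vs),
                            np.asarray(origin), key)
        if kind == "voxel_model":
            vs, origin, freq = _require(
                f.attrs, "voxel_size_mm", "origin_mm", "frequency_Hz")
            return VoxelModel(
                np.asarray(f["speed"]), np.asarray(f["attenuation"]),
                np.asarray(f["density"]), float(vs), np.asarray(origin),
                float(freq))
        if kind == "pressure_plane":
            ps, z, freq = _require(
                f.attrs, "pixel_size_mm", "plane_z_mm", "frequency_Hz")
            return ComplexPressurePlane(
                _read_complex(f, "p"), float(ps), float(z), float(freq),
                origin_xy=np.asarray(f.attrs.get("origin_xy_mm", (0.0, 0.0))))
        if kind == "pressure_volume":
            vs, origin, freq = _require(
                f.attrs, "voxel_size_mm", "origin_mm", "frequency_Hz")
            return ComplexPressureVolume(_read_complex(f, "p"), float(vs),
                                         np.asarray(origin), float(freq))
        if kind == "power_deposition":
            vs, origin = _require(f.attrs, "voxel_size_mm", "origin_mm")
            return PowerDepositionVolume(np.asarray(f["Q"]), float(vs),
                                         np.asarray(origin))
        if kind == "temperature_series":
            vs, origin = _require(f.attrs, "voxel_size_mm", "origin_mm")
            return TemperatureSeries(np.asarray(f["times"]),
                                     np.asarray(f["fields"]), float(vs),
                                     np.asarray(origin))
        raise KeyError(f"unknown container kind {kind!r}")


def _affine(voxel_size, origin):
    aff = np.diag([voxel_size, voxel_size, voxel_size, 1.0])
    aff[:3, 3] = origin
    return aff


def labelmap_to_nifti(label_map: LabelMap, path) -> None:
    img = nib.Nifti1Image(label_map.labels.astype(np.int16),
                          _affine(label_map.voxel_size, label_map.origin))
    img.header.set_zooms((label_map.voxel_size,) * 3)
    nib.save(img, str(path))


def labelmap_from_nifti(path, label_key: dict[int, str]) -> LabelMap:
    img = nib.load(str(path))
    zooms = img.header.get_zooms()[:3]
    if abs(zooms[0] - zooms[1]) > 1e-6 or abs(zooms[0] - zooms[2]) > 1e-6:
        raise ValueError("label map voxels must be isotropic")
    origin = np.asarray(img.affine[:3, 3], dtype=float)
    return LabelMap(np.asarray(img.dataobj).astype(np.int16),
                    float(zooms[0]), origin, label_key)


def volume_to_nifti(values: np.ndarray, voxel_size: float, origin,
                    path) -> None:
    """Export any scalar 3D grid (|p|, Q, a temperature frame) as NIfTI."""
    img = nib.Nifti1Image(np.asarray(values, dtype=np.float32),
                          _affine(voxel_size, np.asarray(origin)))
    img.header.set_zooms((voxel_size,) * 3)
    nib.save(img, str(path))
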