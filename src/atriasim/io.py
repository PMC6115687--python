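"""File formats, run manifests and export plumbing.

Volumes travel as NIfTI (spacing in the header) or multi-page TIFF
(spacing from ImageJ-style metadata or given explicitly); orientation
fields as 4-component NIfTI (three vector components + coherence).
Activation maps are exported as legacy ASCII VTK structured points, a
plain-text format any VTK-based viewer reads.  Every pipeline output
directory carries exactly one JSON run manifest with config snapshot,
input digests and software version.
"""
from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import nibabel as nib
import numpy as np
import tifffile

from .volumes import ImageVolume, LabelVolume, OrientationField

__all__ = [
    "read_volume",
    "write_volume",
    "write_orientation",
    "read_orientation",
    "write_vtk_activation",
    "RunManifest",
    "file_digest",
    "config_digest",
]


def _check_spacing(zooms, path, resample_anisotropic):
    zooms = np.asarray(zooms[:3], float)
    if np.any(zooms <= 0):
        raise ValueError(f"{path}: missing or invalid voxel-size metadata")
    if np.ptp(zooms) > 1e-6 * zooms.mean():
        if not resample_anisotropic:
            raise ValueError(
                f"{path}: anisotropic voxels {tuple(zooms)}; structure-tensor "
                "scales assume isotropic grids — pass resample_anisotropic=True "
                "to resample to the smallest spacing")
        return float(zooms.min()), True
    return float(zooms[0]), False


def read_volume(path, spacing_mm: float | None = None,
                as_labels: bool = False,
                resample_anisotropic: bool = False) -> ImageVolume | LabelVolume:
    """Read a 3D volume from NIfTI (.nii/.nii.gz) or TIFF (.tif/.tiff).

    NIfTI spacing comes from the header; TIFF needs ImageJ metadata or an
    explicit ``spacing_mm``.  Anisotropic voxels raise unless
    ``resample_anisotropic`` is set, in which case the volume is resampled
    to the smallest spacing.
    """
    path = Path(path)
    if path.suffix in (".nii",) or path.name.endswith(".nii.gz"):
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
        spacing, resampled = _check_spacing(img.header.get_zooms(), path,
                                            resample_anisotropic)
        if resampled:
            from scipy import ndimage
            zooms = np.asarray(img.header.get_zooms()[:3], float)
            factors = zooms / spacing
            data = ndimage.zoom(data, factors, order=0 if as_labels else 1)
    elif path.suffix in (".tif", ".tiff"):
        with tifffile.TiffFile(str(path)) as tf:
            data = tf.asarray()
            meta = tf.imagej_metadata or {}
        data = np.moveaxis(data, 0, -1)  # pages are z-planes
        if spacing_mm is None:
            if "spacing" in meta and meta.get("unit", "") in ("mm", "millimeter"):
                spacing_mm = float(meta["spacing"])
            else:
                raise ValueError(
                    f"{path}: TIFF carries no voxel-size metadata; pass "
                    "spacing_mm explicitly")
        spacing = float(spacing_mm)
    else:
        raise ValueError(f"unsupported volume format: {path.suffix!r}")
    if spacing_mm is not None:
        spacing = float(spacing_mm)
    if as_labels:
        return LabelVolume(np.asarray(data).astype(np.int32), spacing)
    return ImageVolume(np.asarray(data, float), spacing)


def write_volume(vol: ImageVolume | LabelVolume, path) -> Path:
    """Write a volume as NIfTI or multi-page TIFF (spacing in the header)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix == ".nii" or path.name.endswith(".nii.gz"):
        affine = np.diag([vol.spacing_mm] * 3 + [1.0])
        data = vol.data
        if isinstance(vol, LabelVolume):
            data = data.astype(np.int32)
        img = nib.Nifti1Image(data, affine)
        img.header.set_zooms((vol.spacing_mm,) * 3)
        nib.save(img, str(path))
    elif path.suffix in (".tif", ".tiff"):
        pages = np.moveaxis(vol.data, -1, 0)
        if isinstance(vol, LabelVolume):
            pages = pages.astype(np.int32)
        else:
            pages = pages.astype(np.float32)  # ImageJ TIFF has no float64
        tifffile.imwrite(str(path), pages, imagej=True,
                         metadata={"spacing": vol.spacing_mm, "unit": "mm"})
    else:
        raise ValueError(f"unsupported volume format: {path.suffix!r}")
    return path


def write_orientation(field_: OrientationField, path) -> Path:
    """4-component NIfTI: vector x, y, z and coherence."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    stack = np.concatenate([field_.vectors, field_.coherence[..., None]], axis=-1)
    affine = np.diag([field_.spacing_mm] * 3 + [1.0])
    img = nib.Nifti1Image(stack, affine)
    img.header.set_zooms((field_.spacing_mm,) * 3 + (1.0,))
    nib.save(img, str(path))
    return path


def read_orientation(path) -> OrientationField:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 4 or data.shape[-1] != 4:
        raise ValueError(f"{path}: expected a 4-component orientation volume")
    spacing = float(img.header.get_zooms()[0])
    return OrientationField(data[..., :3], data[..., 3], spacing)


def write_vtk_activation(times: np.ndarray, model, path,
                         isochrone_interval_ms: float | None = None) -> Path:
    """Legacy ASCII VTK structured points with activation time (NaN encoded
    as -1) plus an activation mask, and optionally isochrone band indices.

    ``model`` is a TissueModel; the arrays are written on its full grid so
    any standard VTK reader can display them.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nx, ny, nz = model.idx_of.shape
    h = model.spacing_mm
    grid_t = np.full((nx, ny, nz), -1.0)
    act_mask = np.zeros((nx, ny, nz), np.int8)
    finite = np.isfinite(times)
    grid_t[model.mask] = np.where(finite, times, -1.0)
    act_mask[model.mask] = finite.astype(np.int8)

    arrays = [("activation_ms", grid_t.ravel(order="F"), "float"),
              ("activated", act_mask.ravel(order="F"), "int")]
    if isochrone_interval_ms:
        from .protocols import ActivationMap, isochrones
        amap = ActivationMap(times, (0.0, float(np.nanmax(times)) if finite.any()
                                     else 0.0), -40.0, h)
        bands, _ = isochrones(amap, isochrone_interval_ms)
        grid_b = np.full((nx, ny, nz), -1, int)
        grid_b[model.mask] = bands
        arrays.append(("isochrone_band", grid_b.ravel(order="F"), "int"))

    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write("atriasim activation map\nASCII\nDATASET STRUCTURED_POINTS\n")
        fh.write(f"DIMENSIONS {nx} {ny} {nz}\n")
        fh.write("ORIGIN 0 0 0\n")
        fh.write(f"SPACING {h} {h} {h}\n")
        fh.write(f"POINT_DATA {nx * ny * nz}\n")
        for name, arr, kind in arrays:
            fh.write(f"SCALARS {name} {kind} 1\nLOOKUP_TABLE default\n")
            fmt = "%.4f" if kind == "float" else "%d"
            np.savetxt(fh, arr.reshape(-1, 1), fmt=fmt)
    return path


# ---------------------------------------------------------------------------
# Run manifests
# ---------------------------------------------------------------------------


def file_digest(path) -> str:
    hsh = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            hsh.update(chunk)
    return hsh.hexdigest()


def config_digest(config: Mapping) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()


@dataclass
class RunManifest:
    """Reproducibility record written once per output directory."""

    config: dict
    seed: int | None = None
    inputs: dict[str, str] = field(default_factory=dict)   # path -> sha256
    outputs: dict[str, str] = field(default_factory=dict)
    software_version: str = ""
    timestamp: str = ""
    extra: dict[str, Any] = field(default_factory=dict)

    def write(self, outdir) -> Path:
        from . import __version__
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.software_version = self.software_version or __version__
        self.timestamp = self.timestamp or time.strftime("%Y-%m-%dT%H:%M:%S")
        path = outdir / "manifest.json"
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, default=str)
        return path

    @staticmethod
    def read(outdir) -> "RunManifest":
        with open(Path(outdir) / "manifest.json") as fh:
            return RunManifest(**json.load(fh))

    def verify_inputs(self) -> bool:
        return all(file_digest(p) == d for p, d in self.inputs.items())
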