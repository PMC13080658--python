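"""Readers and writers for volumes, landmarks, voxel tables and configs.

File-format conventions
-----------------------
* NIfTI-1 (via nibabel) for MRI volumes.  On-disk arrays are (x, y, z) and
  are transposed to the internal (z, y, x) order at the boundary.  Spatial
  units are taken from the header (``meter``/``mm``/``micron``) and converted
  to µm; files written by this package always declare micron units.
* Multi-page TIFF (via tifffile) for microscopy stacks, page order = z.
  Spacing comes from an explicit override, or from ImageJ/resolution tags
  when present; a stack without either is rejected.
* CSV for landmark pairs and voxel tables (comma, decimal point, UTF-8).
* Slicer-style FCSV markups (RAS, mm) are supported as a landmark dialect;
  coordinates are scaled to µm and axis-reversed to (z, y, x), RAS signs are
  kept unchanged.
"""

from __future__ import annotations

import os
import warnings

import numpy as np
import pandas as pd
import yaml

from .core import GeometryError, LandmarkSet, Volume

__all__ = [
    "read_volume",
    "write_volume",
    "read_landmarks",
    "write_landmarks",
    "read_voxel_table",
    "write_voxel_table",
    "load_config",
]

_UNIT_TO_UM = {"meter": 1e6, "mm": 1e3, "micron": 1.0, "unknown": 1.0}


def read_volume(path, format=None, spacing_override=None, dtype_role="intensity"):
    """Read a 3D volume from NIfTI or multi-page TIFF.

    Parameters
    ----------
    path : str or Path
    format : {'nifti', 'tiff', None}
        Inferred from the file suffix when None.
    spacing_override : sequence of 3 floats, optional
        Per-axis spacing in µm, (z, y, x).  Mandatory for TIFF stacks that
        carry no usable resolution metadata; overrides the header otherwise.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if format is None:
        lower = path.lower()
        if lower.endswith((".nii", ".nii.gz")):
            format = "nifti"
        elif lower.endswith((".tif", ".tiff")):
            format = "tiff"
        else:
            raise ValueError(f"cannot infer format of {path!r}; pass format=")
    if format == "nifti":
        return _read_nifti(path, spacing_override, dtype_role)
    if format == "tiff":
        return _read_tiff(path, spacing_override, dtype_role)
    raise ValueError(f"unknown format {format!r}")


def _read_nifti(path, spacing_override, dtype_role):
    import nibabel as nib

    img = nib.load(path)
    data = np.asarray(img.dataobj)
    if data.ndim != 3:
        raise GeometryError(f"expected 3D NIfTI, got ndim={data.ndim}")
    unit = img.header.get_xyzt_units()[0]
    scale = _UNIT_TO_UM.get(unit, 1.0)
    if spacing_override is not None:
        spacing = tuple(float(s) for s in spacing_override)
    else:
        zooms = img.header.get_zooms()[:3]
        spacing = tuple(float(z) * scale for z in reversed(zooms))
    origin_xyz = np.asarray(img.affine[:3, 3], dtype=float) * scale
    origin = tuple(reversed(origin_xyz.tolist()))
    return Volume(np.transpose(data, (2, 1, 0)), spacing, origin, dtype_role=dtype_role)


def _read_tiff(path, spacing_override, dtype_role):
    import tifffile

    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        if data.ndim == 2:
            raise GeometryError(
                "TIFF is a single 2D page; 3D stacks are required "
                "(and spacing must be known)"
            )
        if data.ndim != 3:
            raise GeometryError(f"expected a 3D TIFF stack, got ndim={data.ndim}")
        if spacing_override is not None:
            spacing = tuple(float(s) for s in spacing_override)
        else:
            spacing = _tiff_spacing_from_tags(tif)
            if spacing is None:
                raise GeometryError(
                    f"{path!r} has no usable resolution metadata; pass "
                    "spacing_override=(z, y, x) in um"
                )
    return Volume(data, spacing, dtype_role=dtype_role)


def _tiff_spacing_from_tags(tif):
    """Best-effort spacing (µm) from ImageJ metadata + resolution tags."""
    meta = tif.imagej_metadata or {}
    page = tif.pages[0]
    unit = str(meta.get("unit", "")).lower()
    to_um = {"micron": 1.0, "um": 1.0, "µm": 1.0, "mm": 1e3}.get(unit)
    z = meta.get("spacing")
    xres = page.tags.get("XResolution")
    yres = page.tags.get("YResolution")
    if to_um is None or z is None or xres is None or yres is None:
        return None
    def _res_to_um(tag):
        num, den = tag.value
        return den / num * to_um  # resolution is pixels per unit
    return (float(z) * to_um, _res_to_um(yres), _res_to_um(xres))


def write_volume(volume: Volume, path) -> None:
    """Write a volume to NIfTI (.nii/.nii.gz) or TIFF (.tif/.tiff)."""
    path = os.fspath(path)
    lower = path.lower()
    if lower.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        affine = np.eye(4)
        spacing_xyz = list(reversed(volume.spacing))
        origin_xyz = list(reversed(volume.origin))
        for a in range(3):
            affine[a, a] = spacing_xyz[a]
            affine[a, 3] = origin_xyz[a]
        img = nib.Nifti1Image(np.transpose(volume.data, (2, 1, 0)), affine)
        img.header.set_xyzt_units(xyz="micron")
        img.header.set_zooms(spacing_xyz)
        nib.save(img, path)
    elif lower.endswith((".tif", ".tiff")):
        import tifffile

        sz, sy, sx = volume.spacing
        data = np.asarray(volume.data)
        if data.dtype == np.float64:
            data = data.astype(np.float32)  # ImageJ TIFF has no float64
        elif data.dtype == bool:
            data = data.astype(np.uint8)
        tifffile.imwrite(
            path,
            data,
            imagej=True,
            resolution=(1.0 / sx, 1.0 / sy),
            metadata={"spacing": sz, "unit": "um", "axes": "ZYX"},
        )
    else:
        raise ValueError(f"unsupported volume suffix in {path!r}")


# ---------------------------------------------------------------------------
# Landmarks

_LANDMARK_COLUMNS = [
    "name",
    "fixed_z", "fixed_y", "fixed_x",
    "moving_z", "moving_y", "moving_x",
]


def read_landmarks(path, dialect="csv", moving_path=None) -> LandmarkSet:
    """Read paired landmarks.

    ``csv`` dialect: a single file with columns ``name, fixed_z..fixed_x,
    moving_z..moving_x`` in µm.  ``fcsv`` dialect: two Slicer markups files
    (``path`` = fixed, ``moving_path`` = moving) in RAS mm; converted to µm.
    """
    if dialect == "csv":
        df = pd.read_csv(path)
        missing = [c for c in _LANDMARK_COLUMNS[1:] if c not in df.columns]
        if missing:
            raise ValueError(f"landmark CSV missing columns: {missing}")
        fixed = df[["fixed_z", "fixed_y", "fixed_x"]].to_numpy(dtype=float)
        moving = df[["moving_z", "moving_y", "moving_x"]].to_numpy(dtype=float)
        n_fixed = np.isfinite(fixed).all(axis=1).sum()
        n_moving = np.isfinite(moving).all(axis=1).sum()
        if n_fixed != n_moving or n_fixed != len(df):
            raise ValueError(
                f"mismatched landmark counts: {n_fixed} fixed vs {n_moving} moving"
            )
        names = [str(n) for n in df.get("name", range(len(df)))]
        return LandmarkSet(fixed, moving, names)
    if dialect == "fcsv":
        if moving_path is None:
            raise ValueError("fcsv dialect needs both a fixed and a moving file")
        fixed, names = _read_fcsv(path)
        moving, _ = _read_fcsv(moving_path)
        if len(fixed) != len(moving):
            raise ValueError(
                f"mismatched landmark counts: {len(fixed)} fixed vs "
                f"{len(moving)} moving"
            )
        return LandmarkSet(fixed, moving, names)
    raise ValueError(f"unknown landmark dialect {dialect!r}")


def _read_fcsv(path):
    points, names = [], []
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split(",")
            x, y, z = (float(v) for v in fields[1:4])  # RAS, mm
            points.append((z * 1e3, y * 1e3, x * 1e3))
            names.append(fields[11] if len(fields) > 11 else f"L{len(names)}")
    if not points:
        raise ValueError(f"no landmark rows in {path!r}")
    return np.asarray(points, dtype=float), names


def write_landmarks(landmarks: LandmarkSet, path) -> None:
    fixed = landmarks.fixed_points
    moving = landmarks.moving_points
    df = pd.DataFrame(
        {
            "name": list(landmarks.names),
            "fixed_z": fixed[:, 0], "fixed_y": fixed[:, 1], "fixed_x": fixed[:, 2],
            "moving_z": moving[:, 0], "moving_y": moving[:, 1], "moving_x": moving[:, 2],
        }
    )
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Voxel tables

def write_voxel_table(table: pd.DataFrame, path) -> None:
    """Write a voxel table to CSV; floats survive the round trip to 1e-9."""
    table.to_csv(path, index=False)


def read_voxel_table(path) -> pd.DataFrame:
    return pd.read_csv(path)


def load_config(path) -> dict:
    """Load a YAML configuration file into a plain dict."""
    with open(path, "r", encoding="utf-8") as fh:
        config = yaml.safe_load(fh)
    if config is None:
        config = {}
    if not isinstance(config, dict):
        warnings.warn("config root is not a mapping; wrapping under 'value'")
        config = {"value": config}
    return config
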