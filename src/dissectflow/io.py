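"""File conventions: HDF5 flow containers, NIfTI masks/maps, CSV tables.

A flow series is stored in one HDF5 container with datasets ``/velocity``
([phase, z, y, x, component], m/s) and ``/magnitude`` ([phase, z, y, x])
and root attributes for voxel spacing, temporal resolution, venc and the
RR interval. Masks and parametric maps are NIfTI volumes whose affine is
the diagonal voxel-size matrix (optionally with a translation for maps
defined on a cropped analysis grid), so all volumes of one subject share
physical coordinates.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .phantom import FlowSeries


def save_flow_series(path: str | Path, series: FlowSeries) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("velocity", data=series.velocity, compression="gzip", compression_opts=1)
        f.create_dataset("magnitude", data=series.magnitude, compression="gzip", compression_opts=1)
        f.attrs["voxel_size_mm"] = np.asarray(series.voxel_size_mm)
        f.attrs["temporal_resolution_ms"] = series.temporal_resolution_ms
        f.attrs["venc_cms"] = series.venc_cms
        f.attrs["rr_interval_ms"] = series.rr_interval_ms


def load_flow_series(path: str | Path) -> FlowSeries:
    with h5py.File(path, "r") as f:
        return FlowSeries(
            velocity=f["velocity"][()],
            magnitude=f["magnitude"][()],
            voxel_size_mm=tuple(f.attrs["voxel_size_mm"]),
            temporal_resolution_ms=float(f.attrs["temporal_resolution_ms"]),
            venc_cms=float(f.attrs["venc_cms"]),
            rr_interval_ms=float(f.attrs["rr_interval_ms"]),
        )


def _affine(voxel_size_mm, origin_mm=(0.0, 0.0, 0.0)) -> np.ndarray:
    aff = np.diag([*voxel_size_mm, 1.0])
    aff[:3, 3] = origin_mm
    return aff


def save_volume(
    path: str | Path,
    volume: np.ndarray,
    voxel_size_mm,
    origin_mm=(0.0, 0.0, 0.0),
) -> None:
    """Write a [z, y, x] volume as NIfTI (stored x-fastest, i.e. transposed)."""
    data = np.asarray(volume)
    if data.dtype == bool:
        data = data.astype(np.uint8)
    img = nib.Nifti1Image(np.transpose(data, (2, 1, 0)), _affine(voxel_size_mm, origin_mm))
    nib.save(img, str(path))


def load_volume(path: str | Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Read a NIfTI volume back to [z, y, x] plus its voxel size."""
    img = nib.load(str(path))
    data = np.transpose(np.asanyarray(img.dataobj), (2, 1, 0))
    zooms = img.header.get_zooms()[:3]
    return data, (float(zooms[0]), float(zooms[1]), float(zooms[2]))


def save_mask(path: str | Path, mask: np.ndarray, voxel_size_mm) -> None:
    save_volume(path, mask.astype(np.uint8), voxel_size_mm)


def load_mask(path: str | Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    data, voxel = load_volume(path)
    return data > 0, voxel


def save_centerline_csv(path: str | Path, cl) -> None:
    df = pd.DataFrame(
        {
            "x": cl.points_mm[:, 0],
            "y": cl.points_mm[:, 1],
            "z": cl.points_mm[:, 2],
            "tx": cl.tangents[:, 0],
            "ty": cl.tangents[:, 1],
            "tz": cl.tangents[:, 2],
            "arc_length_mm": cl.arc_length_mm,
        }
    )
    df.to_csv(path, index=False)


def load_centerline_csv(path: str | Path):
    from .geometry import CenterlinePlanes

    df = pd.read_csv(path)
    return CenterlinePlanes(
        points_mm=df[["x", "y", "z"]].to_numpy(),
        tangents=df[["tx", "ty", "tz"]].to_numpy(),
        arc_length_mm=df["arc_length_mm"].to_numpy(),
    )


def save_config_yaml(path: str | Path, config_dict: dict) -> None:
    with open(path, "w") as f:
        yaml.safe_dump(config_dict, f, sort_keys=False)


def load_config_yaml(path: str | Path) -> dict:
    with open(path) as f:
        return yaml.safe_load(f)
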