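"""Voxel-wise hemodynamic maps and per-lumen summaries.

Five parameters are computed for every voxel of the true and false lumen
on a 1 mm isotropic analysis grid, then averaged per lumen:

* kinetic energy (KE): per voxel-phase, 0.5 * rho * dV * |v|^2 with blood
  density rho = 1060 kg/m^3 and dV = 1 mm^3, summed over the included
  cardiac phases and reported in mJ;
* forward / reverse flow (FF / RF): the through-plane flow rate of each
  voxel against its nearest centerline plane, decomposed by sign and
  summed over the cycle, in mL/cycle;
* stasis: percentage of the included phases during which the voxel speed
  is below 0.1 m/s;
* peak velocity (PV): per lumen, the average of the top-5% voxel speeds
  at the phase whose 95th-percentile speed is maximal (phases picked
  independently per lumen), in cm/s;
* kinetic-energy ratio (KER): FL KE divided by TL KE.

A cardiac-cycle cutoff (default 62.9%, the minimum cycle coverage of a
prospectively gated scan) restricts every computation to the first
ceil(fraction * n_phases) phases so that retrospectively and
prospectively gated data are comparable. Scalar summaries are also
reported indexed to the baseline aortic diameter (value / diameter,
per-mm units); the KER, being a pure ratio, is reported unindexed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .geometry import CenterlinePlanes, LumenSegmentation, VoxelPlaneAssignment
from .phantom import FlowSeries, KE_MJ_PER_VOXEL_UNIT_SPEED, STASIS_THRESHOLD_MS

DEFAULT_CYCLE_FRACTION = 0.629


class EmptyLumenError(ValueError):
    pass


@dataclass
class AnalysisGrid:
    """Velocity and masks resampled to a 1 mm isotropic grid.

    ``velocity`` holds only the included phases, in their original order;
    ``included_phases`` are the indices into the source series.
    ``origin_mm`` is the physical (x, y, z) position of grid voxel
    (0, 0, 0) so grid and native coordinates are interchangeable.
    """

    velocity: np.ndarray  # [included_phase, z, y, x, 3] m/s
    tl_mask: np.ndarray
    fl_mask: np.ndarray
    aorta_mask: np.ndarray
    included_phases: list[int]
    dt_ms: float
    origin_mm: np.ndarray
    spacing_mm: float = 1.0

    @property
    def seg(self) -> LumenSegmentation:
        return LumenSegmentation(
            aorta_mask=self.aorta_mask,
            tl_mask=self.tl_mask,
            fl_mask=self.fl_mask,
            voxel_size_mm=(self.spacing_mm,) * 3,
        )


@dataclass
class ParametricMaps:
    ke_map: np.ndarray  # mJ per voxel per cycle
    ff_map: np.ndarray  # mL per voxel per cycle
    rf_map: np.ndarray
    stasis_map: np.ndarray  # percent
    pv_map: np.ndarray  # cm/s


@dataclass
class HemodynamicSummary:
    """Per-lumen scalar results, raw and diameter-indexed."""

    tl: dict
    fl: dict | None
    ker: float | None
    baseline_diameter_mm: float
    indexed: dict = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "TL": self.tl,
            "FL": self.fl,
            "KER": self.ker,
            "baseline_diameter_mm": self.baseline_diameter_mm,
            "indexed_per_mm": self.indexed,
            "flags": self.flags,
        }


def apply_cycle_cutoff(
    series: FlowSeries, fraction: float = DEFAULT_CYCLE_FRACTION
) -> list[int]:
    """Indices of phases whose start time lies before fraction * RR.

    Equivalent to keeping the first ceil(fraction * n_phases) phases.
    """
    if not 0 < fraction <= 1:
        raise ValueError("cycle-cutoff fraction must be in (0, 1]")
    n = series.n_phases
    return list(range(math.ceil(fraction * n - 1e-12)))


def interpolate_to_isotropic(
    series: FlowSeries,
    seg: LumenSegmentation,
    included_phases: list[int] | None = None,
    spacing_mm: float = 1.0,
    margin_voxels: int = 2,
) -> AnalysisGrid:
    """Cubic-spline interpolation of velocities to an isotropic grid.

    The grid covers the aorta bounding box plus a margin; each velocity
    component of each included phase is interpolated with cubic splines
    (`scipy.ndimage.map_coordinates`, order 3) and masks are resampled by
    nearest neighbor so lumen labels stay crisp.
    """
    if included_phases is None:
        included_phases = list(range(series.n_phases))
    sx, sy, sz = series.voxel_size_mm
    if min(sx, sy, sz) < spacing_mm - 1e-9:
        raise ValueError("native voxels already finer than the analysis grid")

    idx = np.argwhere(seg.aorta_mask)
    lo = np.maximum(idx.min(axis=0) - margin_voxels, 0)
    hi = np.minimum(idx.max(axis=0) + margin_voxels, np.array(seg.aorta_mask.shape) - 1)
    native_spacing_zyx = np.array([sz, sy, sx])
    lo_mm = lo * native_spacing_zyx
    hi_mm = hi * native_spacing_zyx

    axes_mm = [np.arange(lo_mm[d], hi_mm[d] + 1e-9, spacing_mm) for d in range(3)]
    grid_shape = tuple(len(a) for a in axes_mm)
    zz, yy, xx = np.meshgrid(*axes_mm, indexing="ij")
    coords = np.stack(
        [zz / native_spacing_zyx[0], yy / native_spacing_zyx[1], xx / native_spacing_zyx[2]]
    )

    velocity = np.empty((len(included_phases), *grid_shape, 3))
    for i, p in enumerate(included_phases):
        for c in range(3):
            velocity[i, ..., c] = ndimage.map_coordinates(
                series.velocity[p, ..., c], coords, order=3, mode="nearest"
            )

    def resample_mask(mask):
        return (
            ndimage.map_coordinates(mask.astype(np.uint8), coords, order=0, mode="nearest") > 0
        )

    origin_mm = np.array([lo_mm[2], lo_mm[1], lo_mm[0]])  # (x, y, z)
    return AnalysisGrid(
        velocity=velocity,
        tl_mask=resample_mask(seg.tl_mask),
        fl_mask=resample_mask(seg.fl_mask),
        aorta_mask=resample_mask(seg.aorta_mask),
        included_phases=included_phases,
        dt_ms=series.temporal_resolution_ms,
        origin_mm=origin_mm,
        spacing_mm=spacing_mm,
    )


def _lumen_speeds(grid: AnalysisGrid, mask: np.ndarray) -> np.ndarray:
    return np.linalg.norm(grid.velocity[:, mask, :], axis=-1)  # [phase, voxel]


def compute_ke_map(grid: AnalysisGrid) -> tuple[np.ndarray, dict]:
    """Cycle-summed voxel-wise kinetic energy (mJ) and per-lumen means."""
    ke_map = np.full(grid.aorta_mask.shape, np.nan)
    per_lumen = {}
    for name, mask in (("TL", grid.tl_mask), ("FL", grid.fl_mask)):
        if not mask.any():
            per_lumen[name] = None
            continue
        speed2 = (grid.velocity[:, mask, :] ** 2).sum(axis=-1)
        ke_vox = KE_MJ_PER_VOXEL_UNIT_SPEED * speed2.sum(axis=0)
        ke_map[mask] = ke_vox
        per_lumen[name] = float(ke_vox.mean())
    return ke_map, per_lumen


def compute_flow_maps(
    grid: AnalysisGrid, assignment: VoxelPlaneAssignment, cl: CenterlinePlanes
) -> tuple[np.ndarray, np.ndarray, dict, dict]:
    """Cycle-summed forward/reverse flow per voxel (mL) and lumen means.

    Per voxel-phase the through-plane flow is q = (v . n) * A * dt with n
    the tangent of the voxel's nearest centerline plane, A = 1 mm^2 the
    voxel cross-section on the 1 mm grid, and dt the temporal resolution.
    Positive q accumulates into FF, negative into RF, so FF - RF equals
    the signed net flow of the voxel exactly.
    """
    ff_map = np.full(grid.aorta_mask.shape, np.nan)
    rf_map = np.full(grid.aorta_mask.shape, np.nan)
    ff_per, rf_per = {}, {}
    area_scale = grid.spacing_mm**2
    for name, mask in (("TL", grid.tl_mask), ("FL", grid.fl_mask)):
        if not mask.any():
            ff_per[name] = rf_per[name] = None
            continue
        planes = assignment.plane_index[mask]
        if np.any(planes < 0):
            raise RuntimeError("luminal voxel without a plane assignment")
        normals = cl.tangents[planes]  # (voxel, 3)
        vn = np.einsum("pvi,vi->pv", grid.velocity[:, mask, :], normals)
        q_mm3 = vn * area_scale * grid.dt_ms  # m/s == mm/ms
        ff_vox = 1e-3 * np.maximum(q_mm3, 0.0).sum(axis=0)
        rf_vox = 1e-3 * np.maximum(-q_mm3, 0.0).sum(axis=0)
        ff_map[mask] = ff_vox
        rf_map[mask] = rf_vox
        ff_per[name] = float(ff_vox.mean())
        rf_per[name] = float(rf_vox.mean())
    return ff_map, rf_map, ff_per, rf_per


def compute_stasis_map(grid: AnalysisGrid) -> tuple[np.ndarray, dict]:
    """Percent of included phases with voxel speed below 0.1 m/s."""
    if grid.velocity.shape[0] < 1:
        raise ValueError("stasis needs at least one included phase")
    stasis_map = np.full(grid.aorta_mask.shape, np.nan)
    per_lumen = {}
    for name, mask in (("TL", grid.tl_mask), ("FL", grid.fl_mask)):
        if not mask.any():
            per_lumen[name] = None
            continue
        speed = _lumen_speeds(grid, mask)
        pct = 100.0 * (speed < STASIS_THRESHOLD_MS).mean(axis=0)
        stasis_map[mask] = pct
        per_lumen[name] = float(pct.mean())
    return stasis_map, per_lumen


def compute_peak_velocity(grid: AnalysisGrid) -> tuple[np.ndarray, dict]:
    """Top-5% mean speed at each lumen's own peak phase, in cm/s.

    The peak phase t* maximizes the 95th percentile of voxel speeds within
    the lumen; t* is chosen independently for TL and FL. The map stores
    every voxel's speed at its lumen's t*.
    """
    pv_map = np.full(grid.aorta_mask.shape, np.nan)
    per_lumen = {}
    for name, mask in (("TL", grid.tl_mask), ("FL", grid.fl_mask)):
        if not mask.any():
            per_lumen[name] = None
            continue
        speed = _lumen_speeds(grid, mask)
        p95 = np.percentile(speed, 95, axis=1)
        t_star = int(np.argmax(p95))
        s_star = speed[t_star]
        k = max(1, math.ceil(0.05 * s_star.size))
        top = np.sort(s_star)[::-1][:k]
        pv_map[mask] = 100.0 * s_star
        per_lumen[name] = float(100.0 * top.mean())
    return pv_map, per_lumen


def compute_parametric_maps(
    grid: AnalysisGrid, assignment: VoxelPlaneAssignment, cl: CenterlinePlanes
) -> tuple[ParametricMaps, dict]:
    ke_map, ke = compute_ke_map(grid)
    ff_map, rf_map, ff, rf = compute_flow_maps(grid, assignment, cl)
    stasis_map, stasis = compute_stasis_map(grid)
    pv_map, pv = compute_peak_velocity(grid)
    per_lumen = {
        name: (
            None
            if ke[name] is None
            else {
                "KE_mJ": ke[name],
                "FF_mL_per_cycle": ff[name],
                "RF_mL_per_cycle": rf[name],
                "stasis_pct": stasis[name],
                "PV_cms": pv[name],
            }
        )
        for name in ("TL", "FL")
    }
    maps = ParametricMaps(
        ke_map=ke_map, ff_map=ff_map, rf_map=rf_map, stasis_map=stasis_map, pv_map=pv_map
    )
    return maps, per_lumen


def summarize(
    per_lumen: dict, baseline_diameter_mm: float
) -> HemodynamicSummary:
    """Assemble raw, ratio and diameter-indexed per-lumen results."""
    if baseline_diameter_mm <= 0:
        raise ValueError("baseline diameter must be positive")
    tl = per_lumen.get("TL")
    fl = per_lumen.get("FL")
    if tl is None:
        raise EmptyLumenError("true lumen summary missing")
    flags = []
    ker = None
    if fl is None:
        flags.append("empty false lumen; KER undefined")
    elif tl["KE_mJ"] <= 0:
        flags.append("TL KE is zero; KER undefined")
    else:
        ker = fl["KE_mJ"] / tl["KE_mJ"]
    indexed = {}
    for name, values in (("TL", tl), ("FL", fl)):
        if values is None:
            continue
        indexed[name] = {k: v / baseline_diameter_mm for k, v in values.items()}
    return HemodynamicSummary(
        tl=tl,
        fl=fl,
        ker=ker,
        baseline_diameter_mm=baseline_diameter_mm,
        indexed=indexed,
        flags=flags,
    )


def export_parametric_maps(
    maps: ParametricMaps, grid: AnalysisGrid, out_dir: str | Path
) -> dict[str, Path]:
    """One NIfTI per parameter (TL and FL overlaid, NaN background) + report."""
    from .io import save_volume

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    names = {
        "kinetic_energy_mJ": maps.ke_map,
        "forward_flow_mL": maps.ff_map,
        "reverse_flow_mL": maps.rf_map,
        "stasis_pct": maps.stasis_map,
        "peak_velocity_cms": maps.pv_map,
    }
    paths = {}
    for name, vol in names.items():
        path = out_dir / f"{name}.nii.gz"
        save_volume(path, vol, (grid.spacing_mm,) * 3, origin_mm=tuple(grid.origin_mm))
        paths[name] = path
    report = {
        name: {
            "lumen_mean": {
                lumen: (float(np.nanmean(vol[mask])) if mask.any() else None)
                for lumen, mask in (("TL", grid.tl_mask), ("FL", grid.fl_mask))
            }
        }
        for name, vol in names.items()
    }
    report_path = out_dir / "parametric_maps_report.json"
    report_path.write_text(json.dumps(report, indent=2))
    paths["report"] = report_path
    return paths
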