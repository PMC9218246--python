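"""Synthetic dissected-aorta 4D flow phantom.

Generates time-resolved three-component velocity volumes for a two-lumen
(true lumen / false lumen) vessel with known, analytically tractable flow,
plus the acquisition corruptions a phase-contrast MRI preprocessing chain
must undo: spatially linear eddy-current velocity offsets, additive noise,
and velocity aliasing (wrap-around at the velocity-encoding limit, venc).

Geometry (default "tangent" style): the dissected aorta is modelled as two
parallel, tangent circular cylinders sharing an axis direction — a true
lumen (TL) of radius ``tl_radius_mm`` and a false lumen (FL) of radius
``fl_radius_mm`` — separated along the intimal-flap normal. A "split" style
(single cylinder of radius ``aorta_radius_mm`` cut in half by the flap
plane) is also available for geometry tests.

Flow model: the TL carries pulsatile axial flow with a parabolic
(Poiseuille-like) cross-sectional profile, peaking at ``tl_peak_speed_ms``.
The waveform is a half-sine systole over the first 40% of the cardiac cycle
followed by a constant low diastolic plateau. The FL carries the same
profile scaled by ``fl_speed_scale``, with the diastolic component reversed
in sign (slow retrograde diastolic filling, so the FL exhibits nonzero
reverse flow). An entry-tear jet — a Gaussian velocity bump directed along
the flap normal — crosses the flap at ``tear_center_mm`` and, at its
default peak of 1.2x venc, aliases when the series is corrupted.

All ground-truth hemodynamic summaries are evaluated directly from the
prescribed velocity field (closed form where available), never through the
measurement pipeline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

BLOOD_DENSITY_KG_M3 = 1060.0
#: KE of a 1 mm^3 voxel moving at 1 m/s: 0.5 * 1060 kg/m^3 * 1e-9 m^3 = 5.3e-7 J
KE_MJ_PER_VOXEL_UNIT_SPEED = 0.5 * BLOOD_DENSITY_KG_M3 * 1e-9 * 1e3
STASIS_THRESHOLD_MS = 0.1  # m/s; a voxel slower than this counts as stagnant


class PhantomConfigError(ValueError):
    """Phantom geometry or waveform configuration is inconsistent."""


@dataclass
class PhantomConfig:
    """Parameters of the synthetic dissected aorta.

    Velocities are in m/s, lengths in mm, times in ms; venc is given in
    cm/s as on the scanner console.
    """

    grid_shape: tuple[int, int, int] = (64, 64, 64)  # (nx, ny, nz)
    voxel_size_mm: float = 2.5
    n_phases: int = 20
    rr_interval_ms: float = 1000.0
    tl_radius_mm: float = 12.0
    fl_radius_mm: float = 16.0
    flap_normal: tuple[float, float, float] = (0.0, 1.0, 0.0)
    tl_peak_speed_ms: float = 1.0
    fl_speed_scale: float = 0.3
    diastolic_fraction: float = 0.1
    systole_fraction: float = 0.4
    tear_center_mm: tuple[float, float, float] | None = None
    tear_jet_speed_ms: float = 1.92  # 1.2 x default venc
    tear_plateau_mm: float = 1.0
    tear_sigma_mm: float = 1.5
    vessel_axis: tuple[float, float, float] = (0.0, 0.0, 1.0)
    vessel_length_mm: float = 160.0
    noise_sigma_ms: float = 0.05
    venc_cms: float = 160.0
    eddy_coeffs: np.ndarray | None = None  # 3x4: per-component a + b*x + c*y + d*z
    rng_seed: int = 0
    profile: Literal["parabolic", "plug"] = "parabolic"
    waveform: Literal["pulsatile", "constant"] = "pulsatile"
    lumen_style: Literal["tangent", "split"] = "tangent"
    aorta_radius_mm: float | None = None  # only for lumen_style="split"

    def __post_init__(self) -> None:
        self.flap_normal = tuple(float(x) for x in _unit(self.flap_normal))
        self.vessel_axis = tuple(float(x) for x in _unit(self.vessel_axis))
        if abs(np.dot(self.flap_normal, self.vessel_axis)) > 1e-8:
            raise PhantomConfigError("flap_normal must be orthogonal to vessel_axis")
        if self.n_phases < 4:
            raise PhantomConfigError("need at least 4 cardiac phases")
        if self.lumen_style == "split" and self.aorta_radius_mm is None:
            raise PhantomConfigError("split lumen style requires aorta_radius_mm")
        extent = min(n * self.voxel_size_mm for n in self.grid_shape[:2])
        width = (
            2.0 * self.aorta_radius_mm
            if self.lumen_style == "split"
            else 2.0 * (self.tl_radius_mm + self.fl_radius_mm)
        )
        if width >= extent:
            raise PhantomConfigError(
                f"lumen width {width:.1f} mm does not fit in grid extent {extent:.1f} mm"
            )

    @property
    def temporal_resolution_ms(self) -> float:
        return self.rr_interval_ms / self.n_phases

    @property
    def venc_ms(self) -> float:
        return self.venc_cms / 100.0


@dataclass
class FlowSeries:
    """Time-resolved 3-component velocity + magnitude volumes.

    ``velocity`` has shape [phase, z, y, x, component] with components
    ordered (vx, vy, vz) in m/s; ``magnitude`` has shape [phase, z, y, x].
    """

    velocity: np.ndarray
    magnitude: np.ndarray
    voxel_size_mm: tuple[float, float, float]
    temporal_resolution_ms: float
    venc_cms: float
    rr_interval_ms: float

    def __post_init__(self) -> None:
        if self.velocity.ndim != 5 or self.velocity.shape[-1] != 3:
            raise ValueError("velocity must be [phase, z, y, x, 3]")
        if self.magnitude.shape != self.velocity.shape[:4]:
            raise ValueError("magnitude must share phase and spatial dims with velocity")
        if not np.all(np.isfinite(self.velocity)):
            raise ValueError("velocities must be finite")

    @property
    def n_phases(self) -> int:
        return self.velocity.shape[0]

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.velocity.shape[1:4]

    @property
    def venc_ms(self) -> float:
        return self.venc_cms / 100.0

    def copy(self) -> "FlowSeries":
        return replace(self, velocity=self.velocity.copy(), magnitude=self.magnitude.copy())


@dataclass
class PhantomTruth:
    """Ground truth accompanying a phantom: masks and reference hemodynamics.

    ``analytic`` holds per-lumen reference values (KE in mJ, FF/RF in
    mL/cycle, stasis in %, PV in cm/s and the FL/TL KE ratio) evaluated
    from the prescribed velocity field over the full cardiac cycle.
    """

    aorta_mask: np.ndarray
    tl_mask: np.ndarray
    fl_mask: np.ndarray
    static_mask: np.ndarray
    analytic: dict
    true_diameter_mm: float


def _unit(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise PhantomConfigError("zero-length direction vector")
    return v / n


def waveform_values(config: PhantomConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Waveforms sampled at phase centres: (TL, FL signed, jet).

    TL: half-sine over the systolic fraction of the cycle, then a constant
    diastolic plateau. FL: same systole, sign-flipped diastole (retrograde
    filling). Jet: systolic half-sine only, silent in diastole. The
    "constant" waveform option is a steady plug of 1 everywhere (no
    retrograde component), used for conservation sanity checks.
    """
    t = (np.arange(config.n_phases) + 0.5) * config.temporal_resolution_ms
    if config.waveform == "constant":
        ones = np.ones(config.n_phases)
        return ones, ones.copy(), ones.copy()
    t_sys = config.systole_fraction * config.rr_interval_ms
    systole = t < t_sys
    w_tl = np.where(systole, np.sin(np.pi * t / t_sys), config.diastolic_fraction)
    w_fl = np.where(systole, np.sin(np.pi * t / t_sys), -config.diastolic_fraction)
    w_jet = np.where(systole, np.sin(np.pi * t / t_sys), 0.0)
    return w_tl, w_fl, w_jet


def _physical_coords(config: PhantomConfig) -> np.ndarray:
    """Voxel-centre coordinates, shape (3, nz, ny, nx), values (x, y, z) mm."""
    nx, ny, nz = config.grid_shape
    s = config.voxel_size_mm
    zz, yy, xx = np.meshgrid(
        np.arange(nz) * s, np.arange(ny) * s, np.arange(nx) * s, indexing="ij"
    )
    return np.stack([xx, yy, zz])


def _build_geometry(config: PhantomConfig):
    """Masks and normalized flow profiles on the phantom grid."""
    nx, ny, nz = config.grid_shape
    s = config.voxel_size_mm
    center = np.array([(nx - 1) / 2 * s, (ny - 1) / 2 * s, (nz - 1) / 2 * s])
    axis = np.asarray(config.vessel_axis)
    nrm = np.asarray(config.flap_normal)

    pos = _physical_coords(config)
    d = pos - center[:, None, None, None]
    ax = np.einsum("i,izyx->zyx", axis, d)
    perp = d - axis[:, None, None, None] * ax
    in_length = np.abs(ax) <= config.vessel_length_mm / 2

    if config.lumen_style == "split":
        r2 = np.einsum("izyx,izyx->zyx", perp, perp)
        disk = (r2 <= config.aorta_radius_mm**2) & in_length
        side = np.einsum("i,izyx->zyx", nrm, perp)
        tl = disk & (side < 0)
        fl = disk & ~tl
        profile_r2 = r2 / config.aorta_radius_mm**2
        tl_profile = np.where(tl, 1.0 - profile_r2 if config.profile == "parabolic" else 1.0, 0.0)
        fl_profile = np.where(fl, 1.0 - profile_r2 if config.profile == "parabolic" else 1.0, 0.0)
        tear_default = center.copy()
        true_diam = 2.0 * config.aorta_radius_mm
    else:
        tl_center = -config.fl_radius_mm * nrm
        fl_center = config.tl_radius_mm * nrm
        d_tl = perp - tl_center[:, None, None, None]
        d_fl = perp - fl_center[:, None, None, None]
        r2_tl = np.einsum("izyx,izyx->zyx", d_tl, d_tl)
        r2_fl = np.einsum("izyx,izyx->zyx", d_fl, d_fl)
        tl = (r2_tl <= config.tl_radius_mm**2) & in_length
        fl = (r2_fl <= config.fl_radius_mm**2) & in_length & ~tl
        if config.profile == "parabolic":
            tl_profile = np.where(tl, 1.0 - r2_tl / config.tl_radius_mm**2, 0.0)
            fl_profile = np.where(fl, 1.0 - r2_fl / config.fl_radius_mm**2, 0.0)
        else:
            tl_profile = tl.astype(float)
            fl_profile = fl.astype(float)
        # tangency point of the two circles, mid-vessel
        tear_default = center + nrm * (config.tl_radius_mm - config.fl_radius_mm)
        true_diam = 2.0 * math.hypot(config.tl_radius_mm, config.fl_radius_mm)

    aorta = tl | fl
    if not tl.any() or not aorta.any():
        raise PhantomConfigError("lumen geometry produced an empty mask")

    tear_center = (
        np.asarray(config.tear_center_mm, dtype=float)
        if config.tear_center_mm is not None
        else tear_default
    )
    # snap to the nearest voxel centre so the jet core reaches full speed
    tear_center = np.round(tear_center / s) * s
    dt = pos - tear_center[:, None, None, None]
    r = np.sqrt(np.einsum("izyx,izyx->zyx", dt, dt))
    # full-speed plateau with Gaussian falloff: the core voxel aliases at
    # jet speeds beyond venc while its neighbours stay unwrapped, which is
    # the regime a neighbourhood-median unwrapping step can repair
    excess = np.maximum(r - config.tear_plateau_mm, 0.0)
    jet_profile = np.exp(-(excess**2) / (2 * config.tear_sigma_mm**2))
    jet_profile = np.where(aorta, jet_profile, 0.0)

    return aorta, tl, fl, tl_profile, fl_profile, jet_profile, true_diam


def _static_tissue_mask(aorta: np.ndarray) -> np.ndarray:
    """A tissue shell around the aorta: zero velocity, moderate signal."""
    from scipy import ndimage

    near = ndimage.binary_dilation(aorta, iterations=2)
    shell = ndimage.binary_dilation(aorta, iterations=6) & ~near
    return shell


def generate_phantom(config: PhantomConfig) -> tuple[FlowSeries, PhantomTruth]:
    """Build the clean (uncorrupted) phantom and its ground truth.

    Deterministic given the config; the rng seed only enters through
    :func:`corrupt_series`.
    """
    aorta, tl, fl, tl_prof, fl_prof, jet_prof, true_diam = _build_geometry(config)
    static_mask = _static_tissue_mask(aorta)
    w_tl, w_fl, w_jet = waveform_values(config)

    axis = np.asarray(config.vessel_axis)
    nrm = np.asarray(config.flap_normal)
    nz, ny, nx = aorta.shape
    velocity = np.zeros((config.n_phases, nz, ny, nx, 3), dtype=np.float64)
    for p in range(config.n_phases):
        axial = (
            config.tl_peak_speed_ms * w_tl[p] * tl_prof
            + config.tl_peak_speed_ms * config.fl_speed_scale * w_fl[p] * fl_prof
        )
        v = axial[..., None] * axis[None, None, None, :]
        if config.tear_jet_speed_ms != 0.0:
            v = v + (config.tear_jet_speed_ms * w_jet[p] * jet_prof)[..., None] * nrm
        velocity[p] = v

    magnitude = np.full(aorta.shape, 0.02)
    magnitude[static_mask] = 0.5
    magnitude[aorta] = 1.0
    magnitude = np.broadcast_to(magnitude, (config.n_phases, *aorta.shape)).copy()

    series = FlowSeries(
        velocity=velocity,
        magnitude=magnitude,
        voxel_size_mm=(config.voxel_size_mm,) * 3,
        temporal_resolution_ms=config.temporal_resolution_ms,
        venc_cms=config.venc_cms,
        rr_interval_ms=config.rr_interval_ms,
    )
    truth = PhantomTruth(
        aorta_mask=aorta,
        tl_mask=tl,
        fl_mask=fl,
        static_mask=static_mask,
        analytic=reference_summary(series, tl, fl, np.asarray(config.vessel_axis)),
        true_diameter_mm=true_diam,
    )
    return series, truth


def reference_summary(
    series: FlowSeries,
    tl_mask: np.ndarray,
    fl_mask: np.ndarray,
    flow_axis: np.ndarray,
    included_phases: list[int] | None = None,
) -> dict:
    """Ground-truth per-lumen hemodynamics from the prescribed field.

    Evaluates the defining formulas of the hemodynamic parameters directly
    on the generator's own velocity arrays, with the known vessel axis as
    the through-plane flow direction. Independent of the measurement
    pipeline (no interpolation, centerline, or plane placement). KE and
    FF/RF use the per-voxel 1 mm^3 / 1 mm^2 bookkeeping of the reported
    parameters, so values are directly comparable with pipeline output.
    """
    phases = (
        list(range(series.n_phases)) if included_phases is None else list(included_phases)
    )
    v = series.velocity[phases]
    dt = series.temporal_resolution_ms
    axis = _unit(flow_axis)
    out: dict = {}
    for name, mask in (("TL", tl_mask), ("FL", fl_mask)):
        if not mask.any():
            out[name] = None
            continue
        vm = v[:, mask, :]  # [phase, voxel, 3]
        speed = np.linalg.norm(vm, axis=-1)
        ke = KE_MJ_PER_VOXEL_UNIT_SPEED * (speed**2).sum(axis=0).mean()
        q = vm @ axis * dt  # mm^3 per phase (m/s == mm/ms, 1 mm^2 area)
        ff = 1e-3 * np.maximum(q, 0.0).sum(axis=0).mean()
        rf = 1e-3 * np.maximum(-q, 0.0).sum(axis=0).mean()
        stasis = 100.0 * (speed < STASIS_THRESHOLD_MS).mean(axis=0).mean()
        p95 = np.percentile(speed, 95, axis=1)
        t_star = int(np.argmax(p95))
        s_star = np.sort(speed[t_star])[::-1]
        k = max(1, math.ceil(0.05 * s_star.size))
        pv = 100.0 * s_star[:k].mean()
        out[name] = {
            "KE_mJ": float(ke),
            "FF_mL_per_cycle": float(ff),
            "RF_mL_per_cycle": float(rf),
            "stasis_pct": float(stasis),
            "PV_cms": float(pv),
        }
    if out.get("TL") and out.get("FL") and out["TL"]["KE_mJ"] > 0:
        out["KER"] = out["FL"]["KE_mJ"] / out["TL"]["KE_mJ"]
    return out


def closed_form_summary(config: PhantomConfig, included_phases: list[int] | None = None) -> dict:
    """Continuum closed-form per-lumen hemodynamics (straight vessel, no jet).

    For a parabolic profile of peak speed ``u`` on a disk, the
    cross-sectional averages are: <v> = u/2, <v^2> = u^2/3, and the speed
    distribution over area is uniform on [0, u] (so the area fraction
    below a threshold c is min(c/u, 1), and the mean of the top 5% of
    speeds is 0.975 u). Only valid for the tangent-cylinder phantom with
    ``tear_jet_speed_ms = 0``.
    """
    if config.tear_jet_speed_ms != 0.0:
        raise PhantomConfigError("closed form requires tear_jet_speed_ms = 0")
    if config.profile != "parabolic" or config.lumen_style != "tangent":
        raise PhantomConfigError("closed form covers the parabolic tangent-cylinder phantom")
    w_tl, w_fl, _ = waveform_values(config)
    phases = (
        np.arange(config.n_phases) if included_phases is None else np.asarray(included_phases)
    )
    dt = config.temporal_resolution_ms
    out: dict = {}
    for name, peak, w in (
        ("TL", config.tl_peak_speed_ms, w_tl[phases]),
        ("FL", config.tl_peak_speed_ms * config.fl_speed_scale, w_fl[phases]),
    ):
        ke = KE_MJ_PER_VOXEL_UNIT_SPEED * (peak**2) * np.sum(w**2) / 3.0
        ff = 1e-3 * dt * (peak / 2.0) * np.sum(np.maximum(w, 0.0))
        rf = 1e-3 * dt * (peak / 2.0) * np.sum(np.maximum(-w, 0.0))
        with np.errstate(divide="ignore"):
            frac = np.minimum(
                np.where(np.abs(w) > 0, STASIS_THRESHOLD_MS / (peak * np.abs(w)), np.inf), 1.0
            )
        stasis = 100.0 * frac.mean()
        pv = 100.0 * 0.975 * peak * np.max(np.abs(w))
        out[name] = {
            "KE_mJ": float(ke),
            "FF_mL_per_cycle": float(ff),
            "RF_mL_per_cycle": float(rf),
            "stasis_pct": float(stasis),
            "PV_cms": float(pv),
        }
    out["KER"] = out["FL"]["KE_mJ"] / out["TL"]["KE_mJ"]
    return out


def wrap_velocity(v: np.ndarray, venc_ms: float) -> np.ndarray:
    """Phase-contrast aliasing: map each component into [-venc, venc).

    Values already inside the encoding range pass through bit-identically;
    +venc lands on -venc (the boundary of the wrap).
    """
    v = np.asarray(v, dtype=float)
    out = v.copy()
    outside = (v >= venc_ms) | (v < -venc_ms)
    out[outside] = np.mod(v[outside] + venc_ms, 2.0 * venc_ms) - venc_ms
    return out


def corrupt_series(
    series: FlowSeries, truth: PhantomTruth, config: PhantomConfig
) -> FlowSeries:
    """Apply acquisition corruptions: eddy offsets, noise, venc wrapping.

    In order: (1) per-component spatially linear offset a + b*x + c*y + d*z
    (coefficients in m/s and m/s per mm) added at every voxel and phase;
    (2) Gaussian noise (sd ``noise_sigma_ms``) wherever there is signal
    (lumens and static tissue) and heavier-tailed uniform phase noise on
    [-venc, venc] in signal-free air; (3) wrap-around of each component
    into [-venc, venc).
    """
    rng = np.random.default_rng(config.rng_seed)
    v = series.velocity.copy()

    if config.eddy_coeffs is not None:
        coeffs = np.asarray(config.eddy_coeffs, dtype=float)
        if coeffs.shape != (3, 4):
            raise PhantomConfigError("eddy_coeffs must be 3x4")
        pos = _physical_coords(config)  # (3, z, y, x) -> (x, y, z) mm
        design = np.concatenate([np.ones((1,) + pos.shape[1:]), pos])  # (4, z, y, x)
        offset = np.einsum("cj,jzyx->zyxc", coeffs, design)
        v += offset[None]

    if config.noise_sigma_ms > 0:
        signal = truth.aorta_mask | truth.static_mask
        noise_in = rng.normal(0.0, config.noise_sigma_ms, size=v.shape)
        v[:, signal, :] += noise_in[:, signal, :]
        noise_out = rng.uniform(-config.venc_ms, config.venc_ms, size=v.shape)
        v[:, ~signal, :] += noise_out[:, ~signal, :]

    v = wrap_velocity(v, config.venc_ms)
    return replace(series, velocity=v, magnitude=series.magnitude.copy())
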