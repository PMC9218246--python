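"""End-to-end orchestration: phantom -> preprocessing -> geometry ->
hemodynamics -> morphometry, plus a synthetic cohort builder for the
statistics layer.

A run is fully described by a :class:`RunConfig`; re-running with the
same config and seed reproduces all numeric outputs bit-for-bit. Every
run directory receives the intermediate artifacts, the final summary
(JSON + CSV) and a provenance record (config hash, package and numpy
versions, seed).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort_stats import (
    InsufficientDataError,
    backward_logistic,
    compare_groups,
    correlate_with_growth,
    univariate_screen,
)
from .geometry import assign_voxels_to_planes, derive_false_lumen, extract_centerline
from .hemodynamics import (
    DEFAULT_CYCLE_FRACTION,
    apply_cycle_cutoff,
    compute_parametric_maps,
    export_parametric_maps,
    interpolate_to_isotropic,
    summarize,
)
from .io import save_centerline_csv, save_flow_series, save_mask
from .morphometry import measure_diameters
from .phantom import PhantomConfig, corrupt_series, generate_phantom, reference_summary
from .preprocess import preprocess_series

logger = logging.getLogger("dissectflow")


@dataclass
class RunConfig:
    """Everything a pipeline run needs, with module defaults in one place."""

    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    corrupt: bool = True
    preprocess: bool = True
    eddy: bool = True
    unwrap: bool = True
    noise_masking: bool = True
    tau_m: float = 0.1
    tau_v_frac: float = 0.3
    cycle_fraction: float = DEFAULT_CYCLE_FRACTION
    out_dir: str = "dissectflow_run"
    save_intermediates: bool = True
    rng_seed: int = 0

    def to_dict(self) -> dict:
        def clean(obj):
            if isinstance(obj, dict):
                return {k: clean(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [clean(v) for v in obj]
            if isinstance(obj, np.ndarray):
                return clean(obj.tolist())
            if isinstance(obj, np.generic):
                return obj.item()
            return obj

        return clean(dataclasses.asdict(self))

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        phantom = d.pop("phantom", {})
        if isinstance(phantom, dict):
            phantom = dict(phantom)
            for key in ("grid_shape", "flap_normal", "vessel_axis", "tear_center_mm"):
                if phantom.get(key) is not None:
                    phantom[key] = tuple(phantom[key])
            if phantom.get("eddy_coeffs") is not None:
                phantom["eddy_coeffs"] = np.asarray(phantom["eddy_coeffs"], dtype=float)
            phantom = PhantomConfig(**phantom)
        return cls(phantom=phantom, **d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as f:
            return cls.from_dict(yaml.safe_load(f))

    def config_hash(self) -> str:
        return hashlib.sha256(
            yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in order; return the results dictionary."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    phantom_cfg = dataclasses.replace(config.phantom, rng_seed=config.rng_seed)

    logger.info("stage simulate: generating phantom %s", phantom_cfg.grid_shape)
    series_clean, truth = generate_phantom(phantom_cfg)
    series = corrupt_series(series_clean, truth, phantom_cfg) if config.corrupt else series_clean
    if config.save_intermediates:
        save_flow_series(out_dir / "flow_series.h5", series)
        save_mask(out_dir / "aorta_mask.nii.gz", truth.aorta_mask, series.voxel_size_mm)
        save_mask(out_dir / "tl_mask.nii.gz", truth.tl_mask, series.voxel_size_mm)
        save_mask(out_dir / "fl_mask.nii.gz", truth.fl_mask, series.voxel_size_mm)

    preprocess_report = None
    if config.preprocess:
        logger.info("stage preprocess")
        series, preprocess_report = preprocess_series(
            series,
            static_mask=truth.static_mask,
            eddy=config.eddy,
            unwrap=config.unwrap,
            noise_masking=config.noise_masking,
            tau_m=config.tau_m,
            tau_v_frac=config.tau_v_frac,
        )

    logger.info("stage geometry + hemodynamics")
    seg = derive_false_lumen(truth.aorta_mask, truth.tl_mask, series.voxel_size_mm)
    included = apply_cycle_cutoff(series, config.cycle_fraction)
    grid = interpolate_to_isotropic(series, seg, included_phases=included)
    cl = extract_centerline(grid.tl_mask, (grid.spacing_mm,) * 3, velocity=grid.velocity)
    cl.points_mm[:] = cl.points_mm + grid.origin_mm  # native physical frame
    assignment = assign_voxels_to_planes(grid.seg, _shifted(cl, -grid.origin_mm))
    maps, per_lumen = compute_parametric_maps(grid, assignment, cl)

    logger.info("stage morphometry")
    max_diameter, fl_diameter = measure_diameters(
        grid.seg, _shifted(cl, -grid.origin_mm), assignment
    )
    summary = summarize(per_lumen, baseline_diameter_mm=max_diameter)

    results = {
        "summary": summary.to_dict(),
        "max_diameter_mm": max_diameter,
        "fl_diameter_mm": fl_diameter,
        "included_phases": included,
        "n_unwrapped_voxels": (
            preprocess_report.n_unwrapped_voxels if preprocess_report else None
        ),
        "reference": reference_summary(
            series_clean,
            truth.tl_mask,
            truth.fl_mask,
            np.asarray(phantom_cfg.vessel_axis),
            included_phases=included,
        ),
        "provenance": {
            "config_hash": config.config_hash(),
            "seed": config.rng_seed,
            "dissectflow_version": __version__,
            "numpy_version": np.__version__,
        },
    }
    (out_dir / "summary.json").write_text(json.dumps(results, indent=2, default=_jsonable))
    _summary_csv(summary, max_diameter, fl_diameter).to_csv(
        out_dir / "summary.csv", index=False
    )
    save_centerline_csv(out_dir / "centerline.csv", cl)
    export_parametric_maps(maps, grid, out_dir / "maps")
    return results


def _shifted(cl, offset):
    import dataclasses as dc

    return dc.replace(cl, points_mm=cl.points_mm + np.asarray(offset))


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _summary_csv(summary, max_diameter, fl_diameter) -> pd.DataFrame:
    rows = []
    units = {
        "KE_mJ": "mJ",
        "FF_mL_per_cycle": "mL/cycle",
        "RF_mL_per_cycle": "mL/cycle",
        "stasis_pct": "%",
        "PV_cms": "cm/s",
    }
    for lumen, values in (("TL", summary.tl), ("FL", summary.fl)):
        if values is None:
            continue
        for key, val in values.items():
            rows.append(
                {
                    "lumen": lumen,
                    "parameter": key,
                    "value": val,
                    "units": units[key],
                    "indexed_per_mm": summary.indexed[lumen][key],
                }
            )
    rows.append({"lumen": "FL/TL", "parameter": "KER", "value": summary.ker, "units": "ratio",
                 "indexed_per_mm": None})
    rows.append({"lumen": "aorta", "parameter": "baseline_diameter", "value": max_diameter,
                 "units": "mm", "indexed_per_mm": None})
    rows.append({"lumen": "FL", "parameter": "fl_diameter", "value": fl_diameter,
                 "units": "mm", "indexed_per_mm": None})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Synthetic cohort for the statistics layer
# ---------------------------------------------------------------------------

#: Generative per-group (mean, sd) for the diameter-indexed parameters,
#: (reference class, event-prone class). Event-prone subjects have larger
#: diameters, lower FL reverse flow and stasis, lower TL KE/FF/PV; rapid
#: growers have a higher FL/TL kinetic-energy ratio.
COHORT_PARAMS: dict[str, tuple[tuple[float, float], tuple[float, float]]] = {
    "fl_rf_mL_per_cycle_per_mm": ((3.13e-4, 1.46e-4), (2.21e-4, 9.44e-5)),
    "fl_stasis_pct_per_mm": ((1.55, 0.46), (1.16, 0.36)),
    "tl_ke_mJ_per_mm": ((2.82e-5, 1.38e-5), (1.86e-5, 1.03e-5)),
    "tl_ff_mL_per_cycle_per_mm": ((2.76e-3, 9.57e-4), (2.04e-3, 7.09e-4)),
    "tl_pv_cms_per_mm": ((5.70, 2.05), (3.84, 1.37)),
    "baseline_diameter_mm": ((41.97, 7.33), (50.50, 6.87)),
    "entry_tear_diameter_mm": ((7.59, 4.0), (11.00, 3.69)),
    "fl_diameter_mm": ((38.33, 8.50), (46.17, 6.77)),
}
KER_BY_GROWTH = ((3.02e-3, 2.34e-3), (4.23e-3, 2.04e-3))  # (slow, rapid)


def make_fixture_cohort(
    n_subjects: int,
    seed: int,
    effect_scale: float = 1.0,
    p_event: float = 12 / 51,
    p_rapid: float = 10 / 42,
) -> pd.DataFrame:
    """Simulate a cohort table with two latent classes.

    Each subject is event-prone (adverse aorta-related outcome, AARO)
    with probability ``p_event`` and a rapid grower with probability
    ``p_rapid``. Hemodynamic and morphometric values are Gaussian with
    class-dependent means; ``effect_scale`` scales the between-class mean
    differences (0 gives a null cohort for calibration checks).
    """
    if n_subjects < 6:
        raise ValueError("need at least 6 subjects")
    rng = np.random.default_rng(seed)
    aaro = rng.random(n_subjects) < p_event
    rapid = rng.random(n_subjects) < p_rapid
    table = pd.DataFrame(
        {
            "subject": [f"S{i:03d}" for i in range(n_subjects)],
            "aaro": aaro.astype(int),
            "rapid_growth": rapid.astype(int),
            "subtype": rng.choice(["tbad", "rtaad"], size=n_subjects, p=[26 / 51, 25 / 51]),
        }
    )
    for var, ((m0, s0), (m1, s1)) in COHORT_PARAMS.items():
        mean = np.where(aaro, m0 + effect_scale * (m1 - m0), m0)
        sd = np.where(aaro, s1, s0)
        table[var] = np.maximum(rng.normal(mean, sd), 0.0)
    (m_slow, s_slow), (m_rapid, s_rapid) = KER_BY_GROWTH
    ker_mean = np.where(rapid, m_slow + effect_scale * (m_rapid - m_slow), m_slow)
    ker_sd = np.where(rapid, s_rapid, s_slow)
    table["ker"] = np.maximum(rng.normal(ker_mean, ker_sd), 1e-6)
    base = np.abs(rng.normal(2.0, 1.5, n_subjects))
    table["growth_rate_mm_per_year"] = np.where(rapid, 3.0 + base, 3.0 - base - 1e-6)
    return table


def analyze_cohort(
    table: pd.DataFrame,
    grouping: str,
    variables: list[str] | None = None,
    subgroup: str | None = None,
) -> dict:
    """Group comparisons, growth correlations and the multivariable model.

    Mirrors the cohort analysis layout: every hemodynamic/morphometric
    variable is compared between the two groups (normality-gated test);
    variables significant on univariate analysis enter backward-stepwise
    logistic regression; each variable is also correlated with growth
    rate when present. Groups with fewer than 3 subjects refuse
    comparison (reported as not performed).
    """
    if subgroup is not None and subgroup != "all":
        table = table[table["subtype"] == subgroup]
    if variables is None:
        variables = [*COHORT_PARAMS.keys(), "ker"]
        variables = [v for v in variables if v in table.columns]
    comparisons, skipped = {}, {}
    for var in variables:
        try:
            comparisons[var] = compare_groups(table, var, grouping)
        except (InsufficientDataError, ValueError) as exc:
            skipped[var] = str(exc)
    correlations = {}
    if "growth_rate_mm_per_year" in table.columns:
        for var in variables:
            try:
                correlations[var] = correlate_with_growth(table, var)
            except (InsufficientDataError, ValueError):
                continue
    candidates = univariate_screen(table, grouping, variables)
    model = backward_logistic(table, grouping, candidates) if candidates else None
    return {
        "grouping": grouping,
        "comparisons": comparisons,
        "skipped": skipped,
        "correlations": correlations,
        "univariate_candidates": candidates,
        "multivariable_model": model,
    }
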