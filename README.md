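# dissectflow

Voxel-wise 4D flow MRI hemodynamics of dissected aortas.

In an aortic dissection, a tear in the intima splits the vessel into a
fast **true lumen (TL)** and a slow, often recirculating **false lumen
(FL)**. Which patients go on to rapid aortic growth or an adverse
aorta-related outcome is poorly predicted by diameter alone, and 4D flow
MRI — time-resolved phase-contrast imaging that encodes a 3D velocity
vector in every voxel over the cardiac cycle — offers hemodynamic
markers that may do better. `dissectflow` implements the full
quantification chain for researchers working with such data: a
synthetic dissected-aorta phantom with known ground truth,
phase-contrast preprocessing, centerline geometry, voxel-wise parametric
maps, growth-rate morphometry, and the cohort-level statistics used to
compare patient groups.

## What it computes

For every voxel inside the TL and FL, on a 1 mm³ isotropic analysis
grid (cubic-spline interpolation from the acquired ~2.5 mm resolution),
over the first ⌈0.629 · n⌉ cardiac phases (a cycle cutoff that makes
prospectively and retrospectively gated scans comparable):

- **Kinetic energy** — KE = ½ ρ dV |v(t)|², ρ = 1060 kg/m³, dV = 1 mm³,
  summed per voxel over the cycle and averaged per lumen (mJ).
- **Forward / reverse flow** — the signed through-plane flow
  q = (v · n̂) A Δt against the nearest of the orthogonal analysis
  planes placed every millimeter along the TL centerline, split by sign
  and cycle-summed (mL/cycle); FF − RF equals the net flow exactly.
- **Stasis** — the percentage of the cycle a voxel's speed stays below
  0.1 m/s.
- **Peak velocity** — the mean of the top-5% voxel speeds at the phase
  whose 95th-percentile speed is maximal, chosen per lumen (cm/s).
- **KER** — the FL/TL kinetic-energy ratio.
- Scalars are also reported indexed to the baseline (maximal) aortic
  diameter, in per-mm units.

Preprocessing reproduces the standard phase-contrast chain: a linear
eddy-current offset fitted on static tissue and subtracted, single-wrap
velocity anti-aliasing against the 6-neighborhood median at
venc = 160 cm/s, noise masking of signal-free regions, and derived
time-averaged magnitude and PC-MRA anatomy images. Morphometry derives
equivalent-area lumen diameters, two-point growth rates over ≥ 180-day
intervals, and the ≥ 3 mm/year rapid-growth classification. The
statistics module provides Shapiro–Wilk-gated t / Mann–Whitney group
comparisons, χ²/Fisher tests, Pearson/Spearman correlation with growth
rate, conditional backward-stepwise logistic regression, noncentral-t
post-hoc power, and the interobserver agreement suite (ICC(2,1),
Bland–Altman, Sørensen–Dice with bootstrap CIs).

## Worked example

Run the full pipeline on the clean straight-tube phantom (64³ voxels at
2.5 mm, 20 phases, parabolic pulsatile TL flow peaking at 1 m/s, FL at
30% with retrograde diastole):

```python
import dissectflow as df
from dissectflow.pipeline import RunConfig, run_pipeline

config = RunConfig(
    phantom=df.PhantomConfig(noise_sigma_ms=0.0, tear_jet_speed_ms=0.0),
    corrupt=False, preprocess=False, out_dir="phantom_demo",
)
results = run_pipeline(config)

s = results["summary"]
print(f"baseline diameter : {results['max_diameter_mm']:.1f} mm")
for lumen in ("TL", "FL"):
    p = s[lumen]
    print(f"{lumen}  KE {p['KE_mJ']:.3e} mJ   FF {p['FF_mL_per_cycle']:.3e} mL/cycle"
          f"   RF {p['RF_mL_per_cycle']:.3e}   stasis {p['stasis_pct']:.1f}%"
          f"   PV {p['PV_cms']:.1f} cm/s")
print(f"KER (FL/TL kinetic energy) : {s['KER']:.3f}")
print(f"indexed TL PV : {s['indexed_per_mm']['TL']['PV_cms']:.3f} cm/s per mm")
```

which prints:

```
baseline diameter : 39.7 mm
TL  KE 7.174e-04 mJ   FF 1.405e-01 mL/cycle   RF 3.754e-06   stasis 52.9%   PV 95.6 cm/s
FL  KE 6.593e-05 mJ   FF 3.920e-02 mL/cycle   RF 3.840e-03   stasis 73.8%   PV 28.7 cm/s
KER (FL/TL kinetic energy) : 0.092
indexed TL PV : 2.412 cm/s per mm
```

Reading the numbers: the TL carries an order of magnitude more kinetic
energy and forward flow than the FL; the FL shows measurable reverse
flow (its retrograde diastolic filling) and much higher stasis; the
measured baseline diameter (39.7 mm) matches the phantom's equal-area
truth of 40 mm. All values agree with the phantom's closed-form truth
to within a few percent (stasis within one percentage point) — the
package's parameter-recovery acceptance band.

A command-line interface mirrors the stages:

```bash
dissectflow run --config run.yaml        # phantom → summary, end to end
dissectflow simulate --out phantom/      # phantom + masks (HDF5/NIfTI)
dissectflow stats --cohort cohort.csv --grouping growth
```

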