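# Methods

This note documents the models, numerical choices and limitations of
`dissectflow` in the package's own terms: what each stage assumes, why
the defaults are what they are, and what the synthetic phantom does and
does not establish about real data.

## The synthetic dissected-aorta phantom

The phantom stands in for a 4D flow acquisition of a dissected
descending aorta. It is deliberately simple enough to admit closed-form
hemodynamic truth, while still containing every feature the analysis
chain must handle: two lumens, pulsatile and retrograde flow, an entry
tear, aliasing, eddy-current offsets and noise.

**Geometry.** Two parallel tangent cylinders share the vessel axis: a
true lumen (TL, radius 12 mm) and a false lumen (FL, radius 16 mm),
separated along the intimal-flap normal. The default radii give an
equal-area outer diameter of 2·√(12² + 16²) = 40 mm, in line with the
baseline diameters of chronic type B dissection cohorts (~42–50 mm),
and keep both lumens well resolved at the 2.5 mm acquired voxel size
(the TL spans ~10 voxels across). A "split" variant — one cylinder cut
in half by the flap plane — is available for geometry tests where the
outer radius must be exactly known. An optional circular-arc tube
exercises the centerline code on curved vessels in the test suite.

**Flow.** The TL carries axial flow with a parabolic (Poiseuille-like)
cross-sectional profile and a waveform consisting of a half-sine
systole over the first 40% of the RR interval followed by a constant
diastolic plateau at 10% of peak. The FL repeats this profile scaled by
0.3 with the diastolic component reversed in sign — slow retrograde
diastolic filling, the simplest mechanism that gives the FL nonzero
reverse flow and higher stasis, in the direction seen in patients. For
the parabolic profile the cross-sectional speed distribution is uniform
on [0, u], which yields the closed forms used as ground truth:
⟨v⟩ = u/2, ⟨v²⟩ = u²/3, stagnant area fraction min(c/u, 1) for a
threshold c, and a top-5% mean of 0.975 u.

**Entry tear.** A jet along the flap normal with a full-speed plateau
(radius 1 mm) and Gaussian falloff (σ = 1.5 mm), centred on the flap at
mid-vessel and snapped to a voxel centre. Its default peak of 1.92 m/s
is 1.2× the 1.6 m/s encoding limit, so the jet core aliases when the
series is corrupted while its neighbours stay unwrapped — exactly the
single-voxel-wrap regime that a neighbourhood-median unwrapping step
can repair. A spatially broad super-venc region would wrap uniformly
and be undetectable by any local method; that failure mode is real but
out of scope for the phantom.

**Corruptions** are applied in the order offset → noise → wrap:
a per-component spatially linear eddy-current field a + bx + cy + dz;
Gaussian velocity noise (default σ = 0.05 m/s) wherever there is signal
(lumens and the static-tissue shell) and uniform noise on [−venc, venc]
in signal-free air, mimicking phase noise where magnitude vanishes; and
wrap-around of each component into [−venc, venc). Values inside the
encoding range pass through bit-identically, so a corruption with zero
noise and zero eddy coefficients is the identity on unaliased data.
Magnitude images are piecewise constant (lumen 1.0, tissue shell 0.5,
air 0.02) — sufficient for the signal-threshold logic they feed, with
no claim to MR signal realism.

**Ground truth** is evaluated two ways, and the two are cross-checked
against each other in the tests: continuum closed forms (valid for the
straight, jet-free parabolic phantom) and direct evaluation of the
defining formulas on the generator's own velocity arrays (valid for any
configuration, including the jet). Neither route touches the
measurement pipeline.

What passing the phantom tests does **not** show: performance on curved,
tapering, branching anatomy; segmentation error (masks are exact here);
realistic MR noise correlations, ghosting, or partial-volume magnitude
effects; respiratory motion. The phantom validates the bookkeeping and
numerics of the quantification, not the imaging physics.

## Preprocessing

**Eddy currents** are modelled as a first-order (spatially linear)
static offset per velocity component, the standard correction for
residual background phase. The time-averaged velocity is regressed on
(1, x, y, z) over static-tissue voxels by least squares and the fitted
plane subtracted from every phase; at least 8 static voxels are
required (2 per coefficient). On the noiseless phantom the injected
coefficients are recovered to machine precision. Static tissue is
supplied explicitly where known; otherwise it is detected as voxels
with temporal velocity sd below 0.02 m/s and time-averaged magnitude
above 30% of the volume's 95th percentile. Near-wall luminal voxels
with vanishing velocity can satisfy this detector; they are genuinely
stagnant and contribute no bias to the fit.

**Anti-aliasing** compares each voxel/component/phase with the median
of its 6-neighborhood (edge-replicated); a discrepancy beyond venc
triggers a single ±2·venc correction toward the median. One correction
per voxel-phase-component recovers any single wrap exactly and the
operation is idempotent on consistent fields.

**Noise masking** flags voxels with time-averaged magnitude below
τ_m = 0.1 of the volume's 95th-percentile magnitude AND temporal
velocity sd (the norm of the per-component sds) above τ_v = 0.3 × venc;
flagged voxels have their velocities zeroed and are never part of a
lumen. The sd statistic evaluates to ≈ venc for uniform phase noise
and to ≈ 0.33 × peak speed for the pulsatile lumen, so 0.3 × venc
separates the two cleanly; a threshold at 0.6 × venc would sit above
the uniform-noise sd of venc/√3 ≈ 0.58 × venc and miss most noise
voxels. A volume whose 95th-percentile magnitude is zero carries no
signal anywhere and is flagged entirely. Zeroing (rather than
excluding) masked voxels is a documented choice; masked voxels are
outside the lumens in all shipped configurations, so luminal averages
are unaffected.

**PC-MRA** is computed as the magnitude-weighted root-mean-square
speed, √(mean_t m² |v|²) — one of several conventional variants; it is
used only for anatomy contrast, and only its lumen-vs-background
contrast is relied upon.

The chain runs eddy correction → anti-aliasing → noise masking. On the
corrupted phantom it strictly reduces the luminal RMS velocity error;
the residual floor is the in-lumen noise itself, which no static
correction removes.

## Centerline and analysis planes

The TL segmentation is skeletonized in 3D; the skeleton voxels form a
26-connected graph with physical edge lengths, and the centerline is
the longest shortest path (the graph diameter, found by a double
Dijkstra sweep). 3D thinning has a degenerate failure: a tube whose
cross-section is exactly even-symmetric has no unique central voxel
layer and can be erased entirely. When the skeleton comes back (near-)
empty, the centerline falls back to a distance-transform ridge
geodesic: edges between mask voxels are weighted by step length divided
by the mean wall distance of their endpoints, so the cheapest path hugs
the medial ridge; the sweep endpoints land on the wall, and the
off-ridge tail (wall distance below 85% of the path maximum, plus
three guard points) is trimmed.

The raw path is smoothed (moving average, window 5), extended to the
mask ends along the principal direction of the terminal ~15 points
(thinning and trimming retreat from the ends by roughly one radius),
smoothed again, and fitted with per-coordinate smoothing splines over
arc length (roughness penalty λ = n, ≈ sub-voxel fidelity). An exact
interpolant is deliberately avoided: voxel-level jitter in the path
becomes lateral wobble of the plane centres, and because FL voxels lie
tens of millimetres from the TL axis, a sub-millimetre lateral outlier
plane can capture thousands of far-lumen voxels under nearest-plane
assignment. The spline is resampled at uniform 1 mm arc length
(spacing accurate to ±0.01 mm via dense arc-length inversion); tangents
are the normalized spline derivatives and serve as plane normals. Point
order is oriented so arc length increases along the mean luminal flow
direction when a velocity field is supplied. Every voxel of both lumens
is assigned to the plane whose centre point is nearest (KD-tree);
plane-centre distance, not perpendicular plane distance, avoids
ambiguity where planes of a curved segment intersect.

## Hemodynamic quantification

All computations run on the 1 mm isotropic analysis grid (cubic-spline
interpolation of each component and phase over the aorta bounding box
plus a 2-voxel margin; masks resampled nearest-neighbour so labels stay
crisp) and on the included-phase set from the cycle cutoff
(⌈fraction · n⌉ leading phases, default fraction 0.629). Unit
bookkeeping: velocities in m/s (≡ mm/ms), voxel volume 1 mm³ = 10⁻³ mL,
KE per voxel-phase 0.5 · 1060 kg/m³ · 10⁻⁹ m³ · |v|² = 5.3 × 10⁻⁴ mJ
at 1 m/s; peak velocities reported in cm/s.

Choices worth stating: "velocity" in the stasis and peak-velocity
definitions is the speed |v|, not an axial component — the parametric
maps are directionless. The cycle cutoff applies uniformly to KE, flow,
the stasis denominator and the PV search window. The top-5% voxel count
is ⌈0.05 N⌉ and percentiles interpolate linearly between order
statistics. The kinetic-energy ratio is reported unindexed — a pure
ratio is diameter-invariant, and dividing it by diameter would silently
change its meaning. Indexed values are raw value / baseline diameter
(per-mm units), exactly invertible.

Interpolating a velocity field that is discontinuous at the lumen wall
necessarily smooths the edge; with the parabolic profile the near-wall
speeds are small, and the residual bias is within the 5% / 1-percentage-
point recovery band on the default phantom. Coarser native resolution
or a blunter true profile would widen it.

## Morphometry

Cross-sections are the voxel sets assigned to each analysis plane; the
cross-sectional area is voxel count × voxel volume / slab thickness,
pooled over a window of adjacent planes at least one native voxel thick
(plane spacing 1 mm against 2.5 mm voxels would otherwise alias the
counts), and the diameter is that of the equal-area circle. The
reported diameter is the maximum over planes, excluding a few planes at
each end where the nearest-plane slab degenerates. Equal-area diameter
was chosen over maximal chord for robustness to voxelization; manual
multiplanar measurements can be supplied as external values instead,
and entry-tear diameter is always an external input. Growth rate is the
two-point slope (last − first diameter over the interval, 365.25
days/year), requires a ≥ 180-day interval, and ≥ 3 mm/year classifies
rapid growth. A regression slope over all serial measurements would be
less noise-sensitive but answers a different question than
diameter-change-over-interval; the two-point convention is kept.

## Cohort statistics

Group comparisons are gated by Shapiro–Wilk at α = 0.05 in each group:
both normal → two-sided pooled-variance t-test (Welch available by
flag), otherwise Mann–Whitney U — exact when both groups have ≤ 20
observations and no ties, else the normal approximation with tie
correction. χ² (no continuity correction) handles categorical
variables, with Fisher's exact substituted for sparse 2×2 tables
(any expected cell < 5). Correlations with growth rate are Pearson by
default, Spearman by option. No multiple-testing correction is applied;
α = 0.05 throughout.

The multivariable model is binary logistic regression over the
univariately significant candidates with conditional backward
elimination: iteratively refit, compute each variable's likelihood-
ratio p against the model without it, and remove the worst while it is
≥ 0.10 (ties broken by larger p, then column order); Wald p-values are
reported for the retained set. The 0.10 removal threshold is the
conventional stepwise default. Separation and non-convergence are
flagged, not raised; perfectly collinear duplicates are removed by the
same LR criterion (removing one costs no likelihood).

Post-hoc power for the two-sample t-test uses the noncentral t:
d = |m₁ − m₂| / s_pooled, δ = d √(n₁n₂/(n₁+n₂)), power =
P(|T′_{df,δ}| > t_crit) with df = n₁ + n₂ − 2. From the published
baseline-diameter group summaries (41.97 ± 7.33, n = 39 vs
50.50 ± 6.87, n = 12) this computes 0.94; computing from the rounded
printed values (42 ± 7 vs 51 ± 7) gives 0.97 — the reported 0.96 sits
between, consistent with rounding of the inputs.

Interobserver agreement uses ICC(2,1) — two-way random effects,
absolute agreement, single measurement — implemented directly from the
ANOVA mean squares so that degenerate inputs (identical observers,
MSE = 0) return exactly 1 rather than 0/0; ICC(3,1) is available by
option, and the implementation is cross-checked against
`pingouin.intraclass_corr` in the tests. Bland–Altman reports bias and
bias ± 1.96 sd of differences; Dice is 2|A∩B|/(|A|+|B|) per lumen with
percentile-bootstrap CIs over subjects (1000 resamples, seeded).

## Synthetic cohort

`make_fixture_cohort` simulates subject tables for exercising the
statistics layer end to end: an event-prone latent class (P = 12/51)
with larger diameters and lower FL reverse flow, FL stasis, TL kinetic
energy, TL forward flow and TL peak velocity, and a rapid-growth class
(P = 10/42) with a higher kinetic-energy ratio. Class-conditional means
and sds are taken from the published cohort's group summaries so that
simulated effect sizes are realistic; `effect_scale` scales the mean
separations (0 gives a null cohort for calibration). Values are
Gaussian draws truncated at zero; growth rate is drawn consistently
with the rapid label. Per-subject phantom image data is not generated
for cohort work — the cohort table is the statistics module's contract
— though individual phantoms can be produced at any size via
`PhantomConfig`.

## Problem sizes and determinism

The shipped configurations are sized for a single CPU: the default
phantom is 64³ voxels × 20 phases (the recovery analysis runs in ~10 s),
statistical calibrations use 2000 null draws and 100 model-selection
simulations, and bootstrap CIs use 1000 resamples. Every stochastic
component takes an explicit seed; the pipeline fans a single run seed
out to the generator, and rerunning a configuration reproduces all
numeric outputs bit for bit.

## Known limitations

Straight-or-gently-curved, branchless vessels only (branch exclusion is
a segmentation-time concern); no wall shear stress or relative pressure
mapping; no concomitant-gradient or B0 corrections; single-venc
encoding only (low venc relative to FL velocities limits the
velocity-to-noise ratio in slow flow, as it does in vivo); the
acquisition is emulated at the velocity-field level, not simulated from
k-space.
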