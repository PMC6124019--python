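# Methods

This note documents the models behind `lungphan4d`: what the digital
phantom emulates, how each derived dataset and statistic is defined, the
numerical choices that matter, and the limits of what the synthetic
pipeline can show about real acquisitions.

## The digital phantom

The phantom is a voxelized stand-in for a commercial respiratory motion
phantom: a rectangular water-equivalent body (0 HU, rounded axial edges,
default 300 × 200 × 260 mm extent) holding a cylindrical low-density
insert along the superior-inferior (SI) axis (radius 40 mm, length
220 mm) that mimics lung, and an offset 3.0 cm sphere mimicking the
tumor. Axes are ordered (lateral, AP, SI); voxel indices are 0-based and
world coordinates refer to voxel centers; the default grid is 1 mm
isotropic.

**Motion.** The target translates along SI as z(t) = A·cos(2πt/T), with
A ∈ {5, 10, 15} mm (half peak-to-peak) and T = 4 s (15 cycles/min).
Phase binning samples the cycle at 10 uniform intervals, so the phase-p
target center sits at A·cos(2πp/10): phase 0 is maximum inhalation (+A),
phase 5 maximum exhalation (−A). Motion is target-only by default: the
lung/body voxels are identical across phases and only the sphere
boundary moves. (A whole-insert mode would mimic the hardware more
literally; target-only isolates the density effect under study and makes
the AIP/MIP datasets analytically checkable.)

**Sphere membership.** A voxel belongs to the target iff its center lies
at Euclidean distance strictly less than r = 15 mm from the sphere
center. The strict rule is deterministic and testable against analytic
volumes (the voxelized sphere volume is unbiased for generic, off-lattice
centers); an optional 2× supersampling flag anti-aliases the boundary by
sub-voxel occupancy blending for users who want partial-volume texture.

**Texture.** Each material carries a Gaussian random field frozen in the
phantom frame: white noise smoothed to a 5 mm-FWHM grain, high-passed at
10 mm, standardized, scaled to sd 25 HU, added to the material mean
(−625 HU lung, −50 HU target) and clipped to the material range
([−750, −600] and [−100, 0]). Three choices deserve explanation:

- *Frozen in the phantom frame*: the physical cedar grain is static, and
  a static field means the MIP dataset takes a maximum over identical
  lung values rather than over independent noise draws — no spurious
  order-statistic inflation.
- *High-pass at 10 mm*: a correlated field keeps slow spatial drift, and
  the mean over a 3 cm sphere would wander by ±10–15 HU from seed to
  seed. Removing components smoother than 10 mm (well above the grain,
  below the target diameter) pins the mean of any target-sized ROI to the
  material mean within a few HU, so the generator's parameters are
  recoverable from its output — a property the test suite checks.
- *Clipping*: the lung range's upper clip sits 1 sd above the lung mean,
  which shifts the realized insert mean to ≈ −627 HU. This is a property
  of the stated range, not an error; all analytic expectations in the
  tests use the realized mean.

Both fields derive from independent sub-streams of one integer seed;
identical seed and spec give bit-identical volumes.

**Free-breathing (FB) dataset.** A helical scan is approximated as a
single-phase snapshot, with the phase drawn reproducibly from the seed
(and recorded in metadata) since the real acquisition's timing is
arbitrary. No helical/motion interplay artifacts are simulated — real FB
scans of a moving target show partial-volume smearing along SI that this
snapshot cannot produce, so FB-derived HU statistics here are idealized
and systematically denser than measured FB scans. Published FB rows
(and the FB-vs-MIP ">200 HU" contrast that depends on them) are
therefore not expectations this phantom can meet; MIP/AIP/PWD statistics
are insensitive to this choice.

## Derived datasets

AIP is the voxelwise arithmetic mean over the 10 phase volumes (uniform
1/10 weights — binning is uniform in phase, no duty-cycle weighting);
MIP is the voxelwise maximum. Both operate on CT numbers directly. With
target-only motion and frozen fields these have closed forms: at a voxel
covered by k of 10 phase spheres, AIP = (k/10)·target + (1−k/10)·lung
and MIP = target wherever k ≥ 1.

## Structures

Phase GTVs are generated geometrically from the known sphere centers
(inter-observer contouring variability is deliberately absent; an
HU-threshold contour is provided for user data). The ITV is the Boolean
OR of the 10 GTVs; the PTV expands the ITV by a 5 mm isotropic margin
implemented as a Euclidean distance transform with a closed-ball
threshold (every voxel whose center lies within 5 mm of a mask voxel).
Because the distance is measured to the *voxelized* mask, whose outer
centers sit up to half a voxel inside the continuous surface, expanded
volumes run ~1–3% small of the ideal ball at 1 mm; the published
plan-parameter volumes are reproduced within their few-percent bands,
which also absorb the 2–3% human-contouring excess in the reference
values.

## Phase-weighted density

The occupancy map k(v) counts covering phase GTVs; its level sets are
exactly the sub-regions a planner would construct by Boolean
addition/subtraction of the 10 contours (the count formulation is
provably equivalent and order-free). The override density is the
occupancy mixture ρ_PWD = (k/10)ρ_GTV + (1−k/10)ρ_lung with
ρ_GTV = −50 HU, ρ_lung = −625 HU by default (estimated from the FB scan
when user data is supplied), applied inside the ITV on the FB base;
outside the ITV the FB voxels pass through bit-exactly. Occupancy is
conserved (Σ_v k = Σ_p |GTV_p|), which forces the ITV mean of ρ_PWD to
equal ρ_lung + (V_GTV/V_ITV)(ρ_GTV − ρ_lung) exactly; and in the
noiseless target-only limit the PWD and AIP datasets coincide voxelwise
inside the ITV — both are computed in float64 so this identity holds to
< 1e-6 HU. Occupancy is quantized to tenths of the period; continuous-
time occupancy from the analytic trajectory is out of scope.

## HU analytics

ROI extraction is mask-based; histograms use fixed bins from −850 to
+50 HU, width 20 (half-open [edge, edge+20), final bin closed), matching
the usual lung-window summary. Values outside the bin range are excluded
from counts but included in mean/sd, since summary statistics must cover
every ROI voxel. The sd is the sample sd (n−1) by default with a
population option; at PTV voxel counts (≳ 45 000) the distinction is
far below reporting precision.

## Dose proxy

The dose engine is a documented toy: D = (MU/500)·B(d_eff)·
exp(−μ_w(d_eff−d_max))·L, with d_eff the water-equivalent depth
(ρ_rel = max(0, 1+HU/1000) accumulated along the axis-aligned beam to
the voxel center), B a saturating buildup reaching 1 at d_max = 1.5 cm
(rate 3 /cm), μ_w = 0.0495 /cm, and L the aperture (fixed 3 × 3 cm²
field or the PTV beam's-eye-view projection) convolved with a 3 mm
Gaussian penumbra, parallel-beam, depth-independent. Calibration is 1.0
arbitrary unit at d_max in water per 500 MU; only relative quantities
are meaningful. There is no scatter superposition, electron transport
or spectral model, so clinical-engine dose differences are explicitly
not reproducible here — the proxy reproduces the *qualitative* point
behaviour: a point upstream of the target is exactly invariant under
target-density overrides, and downstream points respond monotonically
(more attenuation upstream, less dose). Dose is computed on a 2 mm
calculation grid by default. DVH metrics use the top-percentile
convention (D_x% = dose exceeded by x% of the ROI, linear interpolation
on sorted voxel doses); ΔD = 100·(D_A − D_B)/D_A is applied metric-wise
between any two plans. In the pipeline tables each dataset's plan is
compared against the AIP plan with the single toy engine — a
same-formula, different-comparison stand-in clearly labelled in the
output, not an engine comparison.

## Motion blur

A detector riding on the phantom time-averages the static dose over the
cycle, equivalent to convolving the static plane along SI with the
arcsine position density p(x) = 1/(π√(A²−x²)). The kernel is discretized
by exact bin integration of the CDF ½ + asin(x/A)/π, so it sums to 1 by
construction and converges to the identity as A → 0; an empirical
trajectory histogram can substitute for non-ideal traces. Convolution
zero-pads by the kernel half-width and returns the widened plane, so
integral dose is conserved to machine precision rather than clipped at
the film edge.

## Gamma analysis

The gamma index follows the standard dose-difference / distance-to-
agreement formulation: γ(r) is the minimum over displacements of
√(|Δr|²/DTA² + ΔD²/δ²), with δ the dose criterion scaled by the global
reference maximum (default; local normalization available) and a 10%
low-dose threshold excluding points from the statistics — the settings
are logged in the result since commercial film software rarely
documents its own. The evaluated plane is linearly upsampled to a step
≤ DTA/10; the search is capped at 2×DTA, which cannot change pass/fail
(beyond it the distance term alone exceeds 2). The pass test γ ≤ 1
carries a 1e-9 slack for points sitting exactly on the boundary (e.g. a
uniform offset equal to the dose criterion). Gamma is not symmetric in
(reference, evaluated); both orderings are available and labelled. The
implementation is verified against a brute-force per-point oracle in the
test suite; physical film pass-rate tables are not desk-reproducible and
are replaced by these property checks.

## Pipeline, determinism, problem sizes

`full_run` executes 3 motion ranges × 4 datasets and writes the volume,
HU, DVH/ΔD and gamma summary tables, each stamped with a hash of the
resolved config; completed stages are skipped on re-run when the hash
matches. One top-level seed fans out to per-stage sub-streams, so a
repeated run is byte-identical. The default 1 mm run takes ~1.5 min on
one CPU. The test suite exercises the full default-1 mm study for the
structure/HU checks and uses coarser grids (2 mm phantom, 2–4 mm dose)
for the dose, gamma and repeated-run determinism checks — the
scaled-down problems test the same code paths at a fraction of the
cost, and every scale-dependent expectation states its grid.

## Known limitations

- No helical acquisition artifacts, scanner noise spectra, couch
  interplay, irregular breathing or 3D trajectories; FB is a snapshot.
- Structures are geometric; no contouring variability.
- The dose proxy has no scatter or electron transport; absolute dose and
  engine-to-engine differences are out of scope.
- DICOM export writes a geometrically faithful but synthetic CT series;
  there is no RT Structure Set export (masks go out as NIfTI).
- Gamma analysis operates on 2D planes (the film-plane analogue), not
  volumes.
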