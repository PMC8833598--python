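# Methods

## Problem

Microbeam radiotherapy (MRT) delivers kilovoltage X-rays through a lattice of
tens-of-µm-wide planar beamlets spaced hundreds of µm apart. The resulting
dose varies by orders of magnitude (peak vs valley) on a scale far below the
CT voxel, so an MRT plan cannot be compared with a conventional broad-beam
plan dose-for-dose. `mrteud` implements the comparison chain used for such
plans: each CT voxel's microscopic dose distribution is collapsed to the
homogeneous dose with equal clonogenic cell survival under the
linear-quadratic model (the equivalent uniform dose, EUD), converted to the
equivalent dose in 2 Gy fractions (EQD2), and evaluated with the standard
plan-quality machinery (DVHs, D<sub>x%</sub>/D<sub>max</sub>/V<sub>dose</sub>
metrics, organ-at-risk constraint tables).

## Radiobiological model

For a voxel summarized by a dose histogram (w<sub>i</sub>, D<sub>i</sub>)
(volume fraction w<sub>i</sub> at dose D<sub>i</sub>), the survival fraction
is

    SF = Σᵢ wᵢ exp(−α Dᵢ − β Dᵢ²),

and the EUD is the positive root of β E² + α E + ln SF = 0:

    EUD = −α/(2β) + sqrt( (α/(2β))² − ln SF / β ).

Numerics: the SF sum is accumulated in log space (`logsumexp`), so peak doses
of hundreds of Gy never underflow before the logarithm is taken; `exp` of the
result can still underflow to 0 in double precision, which
`survival_fraction` flags with a warning while all downstream arithmetic uses
`ln SF` directly. The root is evaluated in the cancellation-free form
`E = q / (a + sqrt(a² + q))` with `a = α/(2β)`, `q = −lnSF/β`. The β → 0
degenerate case uses the linear limit `E = −lnSF/α`. These choices hold the
closed form to within ~1e-10 Gy of an independent bisection root across
α ∈ [0.01, 0.3] Gy⁻¹, β ∈ [0.005, 0.09] Gy⁻², doses up to 600 Gy (the
acceptance script measures this).

EQD2 of a total dose D delivered in fractions of d Gy:

    EQD2 = D (d + α/β) / (2 Gy + α/β),

with the 2 Gy reference hard-coded. MRT EUD maps are converted with the
single-fraction rule d = D = EUD, reflecting single-session delivery; for the
MRT fraction-dose definition the per-voxel EUD itself is used, since no other
per-fraction dose is defined for a spatially fractionated single exposure.

Tissue parameters (α in Gy⁻¹, β in Gy⁻², ratio in Gy) are looked up
per structure from a CSV registry (`data/tissue_params.csv` ships
literature-style values for common structures); unlabeled voxels default to
α = 0.1 Gy⁻¹, β = 0.05 Gy⁻². Where published tables print a rounded α/β
alongside α and β, the registry derives the ratio from α and β; scalar
prescription conversions accept an explicit ratio. Voxels covered by several
contours (targets overlapping organs at risk are common) are resolved by an
explicit priority list, targets first by default — the overlap rule is an
assumption of this package, not part of the model.

## 35-bin histogram reduction

Subvoxel doses are sorted ascending and split into 35 contiguous groups of
as-equal-as-possible size (equal-count groups; sorting first only matters for
that reading). Each bin carries the group mean dose and the exact group
fraction; when the sample count is not divisible by 35 the remainder goes one
extra sample per group starting from the lowest-dose group, and the last
weight is set to 1 − Σ(others) so the weights sum to exactly 1 in floating
point. Blocks with fewer than 35 samples fall back to one bin per distinct
value. Group means of sorted groups are clamped non-decreasing (division
rounding can perturb equal-valued groups by 1 ulp).

Accuracy: weight and mean conservation are exact to rounding for any block.
The EUD of the 35-bin reduction tracks the un-binned EUD to well under 1%
for bimodal peak/valley mixtures at the dose levels of a normalized plan
(valley-level EUDs ≳ 10 Gy, PVDR up to 100, duty cycles near the 50/400 µm
lattice). For much lower valley doses (≲ 5 Gy) the single group straddling
the valley/peak boundary can distort the (then tiny) survival deficit by
several percent of the EUD — an intrinsic property of the 35-group
reduction, relevant only where doses are far below constraint levels.

## Microbeam dose engine

The engine is a transparent analytic stand-in for full Monte Carlo photon +
electron-kernel transport, and every downstream stage is engine-agnostic (any
producer of subvoxel blocks plugs in). Per coplanar field:

* **Lattice profile** — periodic along the beam's lateral axis: relative dose
  1 inside peaks of width 50 µm (default) every 400 µm, `valley_fraction`
  (default 0.05, a free parameter of the stand-in) in between, anchored with
  a peak plane through the isocenter (phase is not physically constrained;
  zero offset is the convention here). An optional Gaussian penumbra smears
  the peak edges with erf flanks, preserving the period average
  (w + (c − w)·v)/c.
* **Depth dose** — exponential attenuation with one effective coefficient
  (default 0.169 cm⁻¹, water near a 104 keV mean photon energy) applied to
  the radiological depth, the density-weighted path length from the grid
  boundary, traced with an exact Siddon-style voxel traversal. Within a
  parent voxel the depth of each subvoxel sample is corrected to first order
  by local density × along-beam offset.
* **Conformal aperture** — the target volume projected along the beam
  direction onto the beam's-eye plane (voxel centres traced) and dilated by
  one or two pixels; samples outside the aperture get zero dose, or an
  optional uniform scatter fraction.
* **Cross-firing** — fields from several coplanar gantry angles are summed;
  dose is exactly linear in each beam weight.

Known simplifications, stated rather than hidden: no scatter build-up (hence
the PVDR of a single field in homogeneous medium is depth-independent — peak
and valley share the exponential), no spectral hardening, no beam divergence,
no electron-transport blurring beyond the optional penumbra, no lung
microstructure or organ motion.

Subvoxel sampling uses an isotropic 25 µm pitch ("25 µm³" read as a 25 µm
cell size), cell-centred so that whole lattice periods average exactly. Since
the lattice of coplanar beams is invariant along z, the plan-level default
samples one z subdivision per voxel (in-plane 25 µm), configurable back to
fully isotropic. With 2 mm voxels both 400/25 and 50/25 are integers, so the
sampled period average reproduces the analytic 0.16875 at machine precision.

## Plan evaluation

* **DVH** — cumulative % of structure volume at or above each dose, exact
  step curve over the voxel doses.
* **D<sub>x%</sub>** — minimum dose of the hottest x% of the structure
  volume (ICRU-style reading: D2% near-maximum, D98% near-minimum), linear
  interpolation on the cumulative hottest-volume curve; on 100 equal voxels
  at 1..100 Gy this yields D98% = 3 Gy, D2% = 99 Gy. D<sub>V cm³</sub> is the
  analogue for an absolute hottest volume with partial-voxel interpolation;
  V<sub>d Gy</sub> uses whole-voxel counting; V<sub>x%</sub> in constraint
  tables is read as dose-to-x%-volume.
* **Normalization** — MRT plans are scaled so the target D98% of the final
  EQD2(EUD) map matches a reference (e.g. the conventional plan's D98%).
  Because EUD is nonlinear in physical dose, matching is done on the EQD2
  scale by a scalar solve (Brent) over one global beam-weight factor; the
  engine's linearity lets the solve reuse the once-sampled histograms, and
  the achieved D98% is verified to 0.1%. Matching on the reported quantity
  (EQD2 of EUD) rather than physical dose is a design choice of this package.
* **Constraints** — CSV tables (structure, metric, threshold, comparator) on
  the EQD2 scale; reports carry achieved value and pass/fail per row, and can
  be driven either by a dose map or by externally computed achieved values.

## Synthetic phantoms

`generate_phantom` rasterizes a declarative spec: a water cylinder (or slab)
in near-air, a spherical target, labelled spherical/shell organs at risk and
an optional 0.26 g/cm³ lung-like box. The default phantom (80×80×20 mm at
2 mm voxels, ⌀16 mm target, one OAR overlapping the target and one separate)
exercises every pipeline stage including the overlap-priority rule at desk
scale. Generation is deterministic; the seed only drives optional density
noise. What the phantom does **not** emulate: realistic CT heterogeneity,
anatomy-conforming structures, lung microstructure and motion — so passing
tests demonstrate the correctness of the evaluation chain, not clinical dose
accuracy on patient data.

## Problem sizes and defaults

Library defaults: 50/400 µm lattice, valley fraction 0.05, effective
attenuation 0.169 cm⁻¹, 35 bins, 25 µm sampling pitch, dilation 1 voxel.
The packaged end-to-end demonstrations use the default phantom with six
equally spaced beams and in-plane 25 µm sampling (6,400 samples per voxel,
~280 target voxels), which resolves the lattice fully while keeping a full
normalize-and-evaluate cycle in seconds on one core; larger grids and
isotropic z sampling scale linearly.

## Limitations

The engine is not a transport code: absolute depth-dose and PVDR values are
qualitative. LQM validity at very high doses per fraction is debated; peak
bins contribute negligibly to SF, so EUD is insensitive to exactly those
doses. α/β evidence varies between studies; results should be read as
comparisons under a stated parameter set, not absolute outcome predictions.
No dose optimization is performed (beam weights are uniform up to the global
normalization factor), and dose-to-water vs dose-to-medium conversion is out
of scope.
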