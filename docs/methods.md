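# Methods

`canolux` quantifies how faithfully a *virtual* canopy — built by replicating
one, four or eight plants across a plot — reproduces the light interception
of the *realistic*, fully heterogeneous canopy it was taken from. This note
documents the models, the choices behind them, and what the synthetic test
bed does and does not establish about real field data.

## Canopy representation

All canopies are indexed triangle meshes in a plot-local frame: metres, z up,
ground at z = 0, x along the rows (north–south in the simulated fields), y
across rows. Facets carry integer labels (`plant_id`, `organ` with
0 = stem / 1 = leaf / 2 = ground, and `leaf_id`) that serve as ground truth
for every downstream stage. A `CanopyScene` is a set of plant meshes on an
n_rows × n_cols planting grid (defaults 8 × 8, row spacing 0.666 m, plant
spacing 0.266 m, hence ground area S = 5.328 m × 2.128 m), with lateral
domain bounds used for periodic wrapping. Plants sit at
(col · plant_spacing, row · row_spacing) plus jitter; the domain is offset by
half a spacing so each plant is centred in its grid tile and replication
blocks tile the domain exactly.

## Synthetic maize generator

The generator stands in for UAV-reconstructed field canopies.

*Leaf.* The midrib is a planar curve whose tangent angle from vertical grows
linearly with arc length, from the insertion angle to insertion +
curvature · 90°; discretised at equal arc-length steps, the polyline midrib
length equals the nominal leaf length exactly, which makes length a
closed-form-checkable invariant. The lamina is flat across the midrib with
half-width profile w(s) = max_width · sin(πs)^p (p = 0.7 by default); a
rectangular profile variant exists because its area is exactly
length × width, another closed-form anchor.

*Plant.* A coarse hexagonal stem plus alternating-rank leaves whose azimuths
get Gaussian phyllotaxy noise. Leaf sizes follow a mid-stem-heavy profile;
insertion heights span 12–92 % of stem height.

*Stand structure.* Two stage presets emulate a sparse canopy around 48 days
after sowing (8 leaves, ~1.25 m, plot PAI ≈ 1–1.6) and a dense canopy around
70 days (13 leaves, ~2.25 m, PAI ≈ 3–4). Plant-to-plant variability is
multiplicative lognormal on height, leaf length and width, plus jitter on
leaf count, insertion angles and position. Late-stage variability is larger
than early (σ of log length 0.20 vs 0.08): by 70 days competition has
amplified size differences. A plot-level lognormal scale (σ = 0.10) emulates
fertility/treatment differences and is the main source of between-plot
variance. Finally, a border effect makes the outermost plant ring larger and
taller (leaf-area boost 30 % late, 5 % early, half that for the second
ring): border rows of closed canopies face less competition and are
well documented to carry 20–50 % more biomass, and this is exactly why
centre plants — the ones replicated into virtual canopies — are not
representative of the stand. Without this within-plot structure, iid
variability alone makes the early (sparse, linearly responding) canopy the
harder one to replicate, which inverts the stage pattern the method is
meant to expose.

*Point clouds.* Clouds are sampled area-uniformly on mesh surfaces
(Poisson count = density × area), with isotropic Gaussian surface noise
(default σ = 5 mm), a fraction of uniform box outliers (2 %), and occlusion
dropout whose probability rises towards the canopy bottom — the parts a
photogrammetric survey reconstructs worst. True labels are retained
per point. What the generator does **not** emulate: structured
photogrammetric artefacts (doubled surfaces, texture-dependent density),
leaf rolling/serration, tassels and ears, wind deformation. Pipeline
recovery results on these clouds therefore bound discretisation and noise
effects, not full photogrammetric error.

## Cloud-to-mesh pipeline

Statistical outlier removal (mean k-NN distance > mean + ratio·σ, defaults
k = 12, ratio = 2), grid-based slope ground separation (cell 0.25 m,
threshold 30°, with a 3 cm rise tolerance absorbing sensor noise), voxel
downsampling (one centroid per occupied voxel, majority labels; default
voxel 0.02 m — the downsampling scale is interpreted as a metric voxel edge,
with the fraction-of-points reading configurable through the parameter),
then surface triangulation and facet pruning. The base triangulation is a
per-patch 2.5-D Delaunay: points grouped by their (plant, organ, leaf)
labels when present, otherwise by spatial connectivity; each patch is
projected on its principal (SVD) plane, triangulated in 2-D, lifted back,
and edges longer than `max_edge` are not created. Canopy triangulations
produce long sliver facets bridging surfaces; these are removed by the
interquartile-range rule on the per-facet longest edge (area and aspect
statistics selectable): drop facets above Q3 + 1.5·IQR. Congruent-facet
populations (zero IQR) are left intact. Pruning never adds area and is
idempotent on its survivors.

Accuracy is voxel-size-limited in both directions: large voxels smooth away
noise but erode narrow laminae; small voxels track noise bumps and inflate
area. For 5 mm-class noise on 5–8 cm-wide leaves, voxel 10–12 mm with
max_edge 3.5–5 cm recovers total plant area within a few percent; those are
the sizes the recovery tests use.

## Virtual canopies

VCM-n replicates the centre block of a realistic canopy: 1 plant (grid cell
(4,4) on an 8×8 plot under the floor-centre rule), a 2×2 block, or a 2×4
block (the 8-plant arrangement is not uniquely determined by the field
protocol; 2×4 tiles the grid in 8 copies and spans both directions, 1×8 is
selectable). Copies are pure translations placed by block origin, so
within-block jitter and per-plant geometry are preserved exactly and the
result is spatially periodic with the block's period. That periodicity gives
the *clone-tile equivalence*: under periodic boundary conditions,
per-ground-area radiation of the full 64-plant virtual canopy equals that of
the unit block simulated alone on its own tile. The experiment driver uses
the tile by default (it is mathematically equal and ~50× cheaper); the
equivalence itself is verified by a dedicated acceptance test comparing the
full 64-copy simulation against the tile within 1 %.

## Radiation model

Reverse ray tracing on a uniform-grid accelerator (numba kernels,
Möller–Trumbore intersection, 3-D DDA traversal). Rays leaving the lateral
domain re-enter on the opposite side (periodic boundary conditions,
emulating an infinite canopy); geometry overhanging the domain is ghosted by
as many periods as it overhangs. Leaves are two-sided: interception uses
|cos| of the facet-normal/ray angle.

Per time point:

1. **Direct beam.** Each facet casts visibility rays from sub-facet sample
   points (centroid, optionally plus pulled-in edge midpoints in
   deterministic mode; uniform random points in Monte-Carlo mode) towards
   the sun. Intercepted power = DNI · |n·s| · area · visible fraction.
2. **Diffuse sky.** A fixed equal-solid-angle sky dome (elevation bands
   uniform in cos zenith) in deterministic mode, uniform random sky
   directions in MC mode; an isotropic sky radiance D/π is integrated over
   the visible dome.
3. **Scattering.** Each interception splits into absorbed (1 − ρ − τ) and
   scattered (ρ + τ) parts (defaults ρ = τ = 0.1 for the single PAR band;
   ground reflectance 0, configurable). Scattered power is re-emitted
   bi-Lambertian with equal energy from both faces — exact when ρ = τ, an
   average of the two lobes otherwise — over cosine-weighted direction sets
   (equal-energy strata in deterministic mode, with per-facet golden-angle
   azimuth phases; stratified-side cosine sampling in MC mode), traced to
   the next facet, for 8 iterations by default.

**Energy ledger.** "Incident" is defined as the total first-pass intercepted
power (canopy + ground; the sky-side product (B + D)·S is reported as a
diagnostic). Under this definition absorption, scattering, escape and the
truncation residual balance to machine precision, and the residual after k
iterations is bounded by (ρ+τ)^k of the intercepted flux (≈ 2.6·10⁻⁶ at the
default 8 iterations) — each iteration multiplies the in-flight pool by at
most ρ+τ. Facet pools below 10⁻¹¹ of incident are retired into the residual.
An optional `scatter_min_pool` threshold stops iterating once the pool is
negligible (the experiment driver uses 10⁻⁴, which changes DLI by < 0.01 %).

**Sun and sky.** Solar position from the Spencer series (declination,
equation of time) and the hour angle, using local clock time with solar
geometry derived from the longitude (UTC+8 at the default site, 35.3° N /
113.85° E); accuracy is a fraction of a degree. Clear-sky irradiance is a
deliberately simple broadband PAR model: DNI = 1361 W/m² × PAR fraction
0.45 × exp(−0.15 · Kasten–Young airmass), with a fixed diffuse fraction
(0.15) of total horizontal flux. The atmosphere interface is isolated so a
detailed two-band transmittance model can be dropped in; the comparison
conclusions concern *relative* canopy differences, which are insensitive to
absolute atmospheric calibration, and the parameters are documented as
uncalibrated.

**Daily integration.** Thirteen hourly snapshots from 0600 to 1800; DLI is
the trapezoidal time integral (seconds) of canopy-absorbed power over ground
area, reported in MJ m⁻² day⁻¹. (Field reports sometimes print this quantity
with a per-second unit; dimensionally it is a daily areal energy, and that
is the unit used throughout.) Per-facet daily energies are binned by
centroid height into 10 equal-height layers over [0, canopy height]; layer
ratios LR = per-layer share of DLI sum to one whenever DLI > 0.

## Traits

* **PH** — 99th-percentile height minus minimum height
  (linear-interpolation percentile; variants selectable).
* **CC** — occupied 2-D grid cells (default 2 cm) of projected vegetation
  points, divided by the area of the 2-D alpha shape of the projection.
  The alpha shape keeps Delaunay simplices with circumradius ≤ α (default
  α = 2× the 95th-percentile nearest-neighbour distance); since Delaunay
  simplices are interior-disjoint, the area is the sum of kept simplex
  areas. The "occupation area" numerator is a discrete analogue chosen here;
  its cell size is a free parameter and CC is clipped to [0, 1].
* **PAI** — Heron-formula surface area of non-ground facets over ground
  area (leaf facets only when labels exist). Heron is evaluated in Kahan's
  numerically stable form and agrees with the cross-product area to 1e-9.
* **COV** — volume of the 1 cm³ voxels intersecting at least one triangle,
  decided by a conservative separating-axis triangle–box test (a
  vertex-only variant is available and is never larger). The grid is
  anchored at the plot origin, not the mesh bounding box, so grid-aligned
  replicas (the 26.6/66.6 cm spacings are whole centimetres) voxelate
  identically.

## The comparison experiment

For each plot × stage: generate the realistic canopy, build VCM-1/4/8 from
its centre plants, simulate one clear-sky day per canopy (stage dates 2
August and 24 August, 48/70 days after a 15 June sowing), and record DLI,
hourly interception, layer profiles and the trait battery. Agreement is
summarised per variant and per group (both stages pooled, and each stage)
by R² in the model-efficiency form 1 − SSres/SStot — *not* squared Pearson
correlation, so it goes negative when the virtual canopy predicts worse
than the reference mean, which the late stage routinely produces — plus
RMSE and rRMSE = 100·RMSE/mean(reference). Hourly metrics pool all plots
and stages per hour. Realistic-canopy values play the reference role y;
virtual-canopy values are the estimates ŷ.

Default scale: 30 plots × 2 stages, deterministic tracing with 1 direct ray
per facet, 8 sky-dome directions, 2 scattering directions per emitting facet
and the 10⁻⁴ early-stop pool — problem sizes chosen so a full experiment
runs in minutes on one core while leaving the directional findings (error
ordering VCM-1 > VCM-4 > VCM-8; larger late-stage discrepancy for VCM-4/8)
stable; ray-count convergence was checked against denser settings on single
plots.

## Numerical and degenerate-input choices

Ray origins are offset 10⁻⁵ m along the ray and the source facet is
excluded, so sample points on shared edges do not self-intersect; barycentric
tests use a 10⁻⁹ inclusive tolerance so rays cannot leak between facets
sharing an edge. Lateral wraps are capped at 512 per ray (relevant only for
near-horizontal rays on very small tiles; the flux involved is negligible).
The voxel SAT test treats touching within 10⁻¹⁰ m as overlap, keeping
occupancy conservative and symmetric at voxel boundary planes. Zero-DLI days
yield all-zero layer ratios with a warning; constant reference series make
R² undefined (error) rather than silently infinite; empty meshes, degenerate
(collinear) triangulation inputs and invalid parameter ranges raise typed
errors.

## Known limitations

* Leaves are smooth developable strips; no midrib ridge, rolling or
  serration, and no leaf-angle-distribution extraction.
* The scattering redistribution assumes equal-lobe bi-Lambertian re-emission;
  for ρ ≠ τ it averages reflection and transmission rather than tracking the
  incident side.
* The clear-sky model is uncalibrated against any site's atmospheric data;
  absolute DLI values are indicative, relative comparisons are the product.
* Synthetic canopies carry the structural features listed above and no
  others; the directional replication of the field findings shows the
  pipeline produces those patterns under the stated conditions, not that
  the synthetic stand is a statistical twin of any particular field.
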