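# Methods

## Model overview

`coralight` models one corallite-scale patch of coral as a three-phase
voxel volume (seawater, living tissue, aragonite skeleton), propagates a
collimated downwelling beam through it with a voxel Monte Carlo method, and
converts the resulting relative fluence rate Φ into a relative gross
photosynthesis score per tissue voxel. Two parameter sets — a shallow and a
mesophotic *Stylophora pistillata* morphotype — are compared across
irradiance levels, optical scenarios and structural variants.

## Geometry

A tile is a square corallite lattice at pitch CSC. Each corallite is a
cylindrical calyx of diameter CD recessed TH below the coenosteum plane,
with n (default 6) thin radial septa (length SL, width SW, spanning the
calyx depth) and a central columella cylinder (height CH, diameter CD/6 by
default — the diameter is not a measured trait). The coenosteum is studded
with conical spines (height SPL, base width SPW) on a lattice whose pitch
is snapped to divide the tile edge, so tiles are laterally periodic by
construction. Below the calyx floor the skeleton continues as a solid slab
(default 0.3 mm) terminated by an absorbing plane. Voxels are isotropic
(default 0.02 mm); the z axis points down from the top of the water column.

**Tissue surface.** Two contracted-tissue conventions are implemented:

- `drape` (default): a constant-thickness tissue layer — thickness equal to
  the maximal coenosteal spine length, per the tissue-thickness rule —
  follows the entire skeletal relief: it tops the coenosteum at spine-tip
  height and lines the calyx walls and floor, leaving the corallite as a
  cup-shaped depression in the tissue–water interface.
- `filled`: the calyx cavity is filled with tissue flush with the theca
  rim, leaving only a shallow (spine-height) depression.

The drape is the default because it is the configuration in which the two
morphotypes behave as the measured colonies do. With a flush fill, the
tissue inside the deep shallow-morphotype calyx sits in a cavity of
high-albedo scattering skeleton and its fluence *rises* with depth (an
integrating-cavity effect): mean tissue Φ is then higher for the shallow
morphotype under every boundary condition and slab thickness we examined,
the high-/low-light score ordering between morphotypes inverts, and the
rugosity contrast between morphotypes nearly vanishes. With the drape,
vertical wall tissue receives no direct beam at normal incidence, surface
rugosity of the shallow morphotype exceeds the mesophotic by the expected
~1.5–2×, and the depth-adaptation orderings emerge. The tests assert these
orderings; the `filled` variant remains available for comparison.

**Simulation domain.** The default transport domain is a single corallite
tile with absorbing lateral boundaries. A corallite on a curved branch is
not an element of an infinite plane lattice; laterally escaping diffuse
light is genuinely lost to neighbouring water. Periodic boundaries (which
model an infinite flat lattice and are supported, exploiting the tile's
construction-time periodicity) suppress this loss pathway and with it the
self-shading distinction between morphotypes. Multi-corallite tiles and
periodic transport remain config options.

**Surface metrics.** The tissue–water interface is a heightfield by
construction; its area is computed from a periodic triangulation of the
per-column surface height (exact for a flat slab; within 3% of the
closed form for a hemispherical bump at 0.005 mm resolution). Rugosity is
real area / planar tile area, hence ≥ 1 — note the ratio is reported in
this orientation throughout. Skeletal porosity is the water fraction of the
skeleton envelope (per column, from the topmost skeleton voxel down); the
default geometry is non-porous and transport treats the skeleton as
homogeneous, with a stochastic spherical-pore generator provided solely to
exercise the metric.

**Knock-outs and exchanges.** `knockout:columella` and `knockout:spines`
omit the feature (the coenosarc keeps the thickness the spines would have
set). `knockout:corallite` flattens the tile and thickens the coenosarc so
total tissue volume matches the default tile; the final partial voxel layer
is distributed by a deterministic spatial hash, making the match exact to
one voxel (well within the 1% contract). Trait exchanges swap the spacing
pair (CSC, CSM) or the theca height TH between morphotypes; the spacing
pair is swapped together so the lattice constraint CSM ≤ CSC − CD survives
the swap and the exchange is involutive.

## Optics

Scenario 1 (defaults): µs′ skeleton 15 cm⁻¹, µs′ tissue 10 cm⁻¹, µa tissue
1.18 cm⁻¹, µa skeleton 0.01 cm⁻¹, g = 0.9 for both phases. Scenarios 2–6
vary one property at a time (tissue µa ×0.5 and ×10, tissue µs′ ×0.1,
skeletal µa high — 1.0 cm⁻¹, an assumed value — and skeletal µs′ ×0.2).
Configs accept reduced scattering and convert via µs = µs′/(1 − g),
preserving transport-equivalent scattering. Water is nearly transparent
(µa 0.001 cm⁻¹, µs′ 0.01 cm⁻¹ — assumed). Refractive indices are matched
everywhere: no Fresnel reflection or refraction is modelled.

## Transport numerics

Photon packets launch uniformly over the top face travelling +z. Free
paths are sampled in optical depth and walked voxel-by-voxel with partial
steps at media crossings (a 1 nm nudge moves packets across faces; its
bias is ~10⁻⁶ relative). At an interaction, the fraction µa/µt of the
packet weight is deposited and the remainder scatters through the
Henyey–Greenstein inverse CDF with uniform azimuth. Packets below weight
10⁻⁴ undergo Russian roulette with survival probability 0.1 (standard
values; the net weight the roulette creates/destroys is tracked, so the
ledger launched = absorbed + escaped + roulette-residual closes to float
precision, and the residual itself is ~10⁻⁷ at 10⁶ packets).

Fluence uses a track-length estimator — track length per voxel, per voxel
volume, per incident packet areal density — so a non-interacting medium
yields Φ = 1 in the beam; it is valid at µa = 0. An absorbed-weight
estimator (A/(µa V N)) is available where µa > 0 and agrees with the
track-length estimator within Monte Carlo error. Randomness is
counter-based: each packet's stream is keyed by (seed, packet index)
(splitmix64-seeded xorshift64*), so results are independent of batching
and exactly reproducible per seed.

Verification: an absorbing-only slab reproduces exp(−µa z) within 2% to
three optical depths at 10⁶ packets; depth profiles in a layered medium
match an independent continuous-space reference implementation; the HG
sample mean equals g within 3 standard errors at 10⁶ draws; halving the
voxel size changes mean tissue Φ by < 3%.

## Photosynthesis

P(E) = P_max (E/E_opt) exp(1 − E/E_opt), evaluated at E = E0 Φ per tissue
voxel and averaged over tissue voxels. E0, E and E_opt share units
(µmol photons m⁻² s⁻¹); the relation is scale-consistent, and scores are
relative — no absolute O₂ calibration is attempted. Default irradiances
are 750 (≈5 m) and 45 (≈50 m) µmol photons m⁻² s⁻¹. The two P–E fixture
sets are assumed values (shallow: P_max 1.0, E_opt 300; mesophotic:
P_max 0.8, E_opt 80 µmol photons m⁻² s⁻¹), ordered as high- vs low-light
acclimated symbionts and config-overridable; all conclusions drawn from
them in this package are directional or bounded, not point estimates.

## Trait fixtures and the synthetic generator

Per-morphotype trait means ship in `src/coralight/data/morphotypes.yaml`
with provenance tags: CD (1.02 / 0.63 mm), the CSM contrast (0.24 /
0.38 mm, +58%) and porosity (8.28% / 15.57%) are anchored to measured
values; the remaining traits are plausible assumed values. The synthetic
generator emulates the study design — two depth groups, 15 colonies per
group, ≥10 replicate measurements per trait — with additive normal colony
effects truncated at zero (traits are positive lengths) and multiplicative
lognormal replicate noise at a stated CV (defaults: colony SD 10% of the
pooled mean, CV 5%; within-colony variance is not reported anywhere, so
these are design choices). Per-colony Philox streams are keyed by (seed,
colony index): growing the design never reshuffles earlier colonies.

What the generator does not emulate: intra-branch positional gradients,
trait–trait correlation within groups beyond what the group contrast
induces, measurement-device bias, or non-normal colony effects. Passing
statistics tests therefore demonstrate calibration and power under this
idealized design, not under every real measurement structure.

## Statistics

Replicates are collapsed to colony means before any inference; colonies
are the experimental unit. The univariate group test permutes whole
colonies across depth groups (the permutational analogue of a sample-ID
random effect — a deliberate simplification of a mixed-effects
permutational model, with the same inferential target). Permutation
p-values use the add-one correction, p = (1 + #{|d*| ≥ |d|})/(1 + n_perm),
guaranteeing p > 0; at α = 0.05 the decision rule p ≤ α is exact on the
add-one grid. Multivariate analyses standardize traits to pooled zero
mean/unit variance, use Euclidean distances, drop zero-variance traits
with a warning, and clamp any negative eigenvalues (impossible for
Euclidean input) to zero. PCoA is classical scaling via scikit-bio, with a
loadings proxy (trait–axis Pearson correlations; the 10% "null
contribution" threshold is a reporting flag, not a test). PERMANOVA
partitions the squared-distance matrix into among/within sums of squares;
for ≤ 8 colonies an exhaustive enumeration over all label assignments
replaces sampling. SIMPER decomposes the mean between-group squared
Euclidean distance into additive per-trait components summing to 100%.

## Problem sizes

Desk defaults: 0.02 mm voxels, one corallite per tile (65–70 voxels on a
side, ~0.5 M voxels), 10⁶ photon packets per run (~3–4 s on one CPU core),
three to five seeds per contrast; statistical calibration uses 500
simulated null tables. Finer grids (down to 0.005 mm), larger tiles and
larger packet counts are config presets; the directional contrasts
reported by the tests are stable under grid refinement and across seeds.

## Known limitations

- The tissue is one homogeneous phase: no chlorophyll gradients, no
  epidermis/gastrodermis layering, no expansion/contraction dynamics.
- No refractive-index mismatch, polarization, fluorescence or non-HG phase
  functions; illumination is a normal-incidence collimated beam only.
- The corallite lattice is square (hexagonal packing is not implemented);
  septa are rectangular ridges; spine and columella shapes are idealized.
- P–E parameters and several trait means are assumed fixtures; absolute
  score magnitudes are therefore not comparable to measured rates — only
  contrasts between morphotypes run under identical assumptions are.
- Skeletal porosity is a reporting metric; transport always sees a
  homogeneous skeleton.
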