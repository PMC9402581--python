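# coralight

Corallite-scale light capture and photosynthesis modelling for the
depth-generalist coral *Stylophora pistillata*.

Reef-building corals from shallow (~5 m) and mesophotic (~50 m) depths grow
distinct corallite morphotypes: shallow colonies build wide, deep, closely
spaced corallites, while mesophotic colonies build smaller, shallower, more
widely spaced ones. `coralight` asks what these micro-skeletal differences
do to the light actually available to the symbiont-bearing tissue, and to
photosynthesis, at each depth's irradiance.

The package provides:

- **Parametric voxel geometry** (`coralight.geometry`): a corallite lattice
  tile built from ten trait means (calyx diameter CD, theca height TH,
  septal length/width SL/SW, columella height CH, coenosteal spine spacing/
  length/width SS/SPL/SPW, corallite spacing CSC/CSM), with a contracted
  tissue layer draped over the skeletal relief, feature knock-outs
  (corallite, columella, spines), trait exchanges between morphotypes, and
  surface metrics (area, rugosity, tissue volume, skeletal porosity).
- **Voxel Monte Carlo photon transport** (`coralight.mc`): collimated
  normal-incidence illumination, per-phase absorption and scattering
  (configured as µa and reduced scattering µs′ in cm⁻¹, with
  Henyey–Greenstein anisotropy g), track-length fluence-rate estimation
  (Φ relative to the incident irradiance), Russian roulette, and an exact
  energy ledger. The numba kernel runs ~10⁶ photons on a corallite tile in
  a few seconds; a counter-based per-photon RNG makes runs reproducible.
- **Photosynthesis scoring** (`coralight.photosynthesis`): the peaked P–E
  relation `P = P_max (E/E_opt) exp(1 − E/E_opt)` applied per tissue voxel
  at `E = E0 Φ`, summarized per tissue voxel.
- **Scenario matrix** (`coralight.pipeline` + `coralight` CLI): morphotype
  × irradiance (750 / 45 µmol photons m⁻² s⁻¹) × six optical scenarios ×
  two P–E sets × structural variants, with per-run seeds and tidy CSV
  output.
- **Morphometric statistics** (`coralight.morphometrics`) on trait tables:
  group summaries, colony-block permutation tests, PCoA, PERMANOVA, SIMPER
  and Pearson correlations — colonies are the experimental unit throughout.
- **Synthetic trait tables** (`coralight.synthetic`): two depth groups with
  colony-level random effects and lognormal replicate noise, so the whole
  statistics stack is testable without any raw data.

## Worked example

```python
import coralight as cl
from coralight.pipeline import load_optical_scenarios
from coralight.photosynthesis import load_default_pe, score_volume

morphs = cl.load_default_morphotypes()
optics = load_optical_scenarios()[1]          # default bio-optics
pe = load_default_pe()
for name in ("shallow", "mesophotic"):
    tile = cl.build_tile(morphs[name])        # 0.02 mm voxels, 1 corallite
    flu = cl.run_mc(tile, optics, cl.TransportConfig(
        n_photons=1_000_000, seed=0, lateral_boundary="absorbing"))
    print(name, round(cl.surface_metrics(tile).rugosity, 2),
          round(cl.mean_tissue_phi(flu, tile), 2))
    for E0 in (750.0, 45.0):
        for pset in ("shallow", "mesophotic"):
            s = score_volume(flu, tile, pe[pset], E0)
            print(f"  E0={E0:>5.0f} {pset:>10s} P-E: {s.summary:.4f}")
```

prints

```
shallow 1.68 1.3
  E0=  750    shallow P-E: 0.3554
  E0=  750 mesophotic P-E: 0.0003
  E0=   45    shallow P-E: 0.4337
  E0=   45 mesophotic P-E: 0.7594
mesophotic 1.05 1.37
  E0=  750    shallow P-E: 0.3109
  E0=  750 mesophotic P-E: 0.0002
  E0=   45    shallow P-E: 0.4546
  E0=   45 mesophotic P-E: 0.7710
```

Read: the shallow architecture is ~1.6× more rugose and keeps less light
per tissue voxel (mean Φ 1.30 vs 1.37) — its deep, closely packed corallite
cups self-shade. Under high light (750) that pays off: the shallow
morphotype scores higher with either P–E set (0.355 > 0.311), because its
shaded tissue sits closer to the photosynthetic optimum while the flatter
mesophotic tissue is photoinhibited. Under low light (45) the ordering
reverses (0.759 < 0.771, 0.434 < 0.455): the open mesophotic architecture
captures scarce photons more evenly. Scores are relative (multiples of the
P–E set's scale), normalized per tissue voxel.

The same contrasts are available from the shell:

```bash
coralight run-matrix --out-csv results.csv --seed 0
coralight report results.csv
```

and the statistics stack runs on any tidy trait CSV
(`sample_id, depth_group, trait, replicate_index, value, units`):

```bash
coralight generate-traits --out traits.csv --seed 0
coralight stats traits.csv --out-dir statsout
```

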