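"""Scenario-matrix orchestration: morphotype x irradiance x optics x P-E
x structural variant, with per-run seeds and result aggregation.

The default ledger crosses both morphotypes, both irradiance levels and
both P-E sets with the six optical scenarios (default structure), and adds
the structural variants (feature knock-outs and trait exchanges) under the
default optical scenario only.  Fluence volumes depend only on (geometry,
optical scenario, transport seed), so they are cached and re-scored across
irradiance levels and P-E sets.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import geometry as geo
from . import photosynthesis as ps
from .mc import MediumOptics, OpticalProperties, TransportConfig, mean_tissue_phi, run_mc

logger = logging.getLogger(__name__)

MORPHOTYPES = ("shallow", "mesophotic")
IRRADIANCE_LEVELS = ("high", "low")
PE_SETS = ("shallow", "mesophotic")
STRUCTURAL_VARIANTS = (
    "default",
    "knockout:corallite",
    "knockout:columella",
    "knockout:spines",
    "exchange:spacing",
    "exchange:height",
)


class PipelineError(ValueError):
    """Invalid scenario configuration."""


@dataclass(frozen=True)
class ScenarioSpec:
    morphotype: str
    irradiance_level: str      # "high" (750) or "low" (45)
    optical_scenario: int      # 1..6
    pe_set: str                # which P-E parameter set
    structural_variant: str
    replicate_seed: int

    def __post_init__(self) -> None:
        if self.morphotype not in MORPHOTYPES:
            raise PipelineError(f"unknown morphotype {self.morphotype!r}")
        if self.irradiance_level not in IRRADIANCE_LEVELS:
            raise PipelineError(f"unknown irradiance level {self.irradiance_level!r}")
        if self.optical_scenario not in range(1, 7):
            raise PipelineError(f"optical_scenario must be 1..6, got {self.optical_scenario}")
        if self.pe_set not in PE_SETS:
            raise PipelineError(f"unknown pe_set {self.pe_set!r}")
        if self.structural_variant not in STRUCTURAL_VARIANTS:
            raise PipelineError(f"unknown structural_variant {self.structural_variant!r}")


def load_optical_scenarios(path: str | Path | None = None) -> dict[int, OpticalProperties]:
    """Load the shipped six-scenario optics ledger (entries are µs')."""
    if path is None:
        path = Path(__file__).parent / "data" / "optics.yaml"
    raw = yaml.safe_load(Path(path).read_text())
    g = float(raw["g"])
    water = MediumOptics.from_reduced(raw["water"]["mua"], raw["water"]["mus_prime"], g)
    out = {}
    for sid, entry in raw["scenarios"].items():
        out[int(sid)] = OpticalProperties(
            water=water,
            tissue=MediumOptics.from_reduced(entry["tissue"]["mua"], entry["tissue"]["mus_prime"], g),
            skeleton=MediumOptics.from_reduced(entry["skeleton"]["mua"], entry["skeleton"]["mus_prime"], g),
        )
    return out


def default_config() -> dict:
    """Full default configuration for the scenario matrix."""
    return {
        "geometry": {
            "resolution": 0.02,          # mm per voxel
            "tile_corallites": 1,
            "water_above": 0.3,
            "slab_below": 0.3,
            "tissue_surface": "drape",
        },
        "transport": {
            "n_photons": 1_000_000,
            "lateral_boundary": "absorbing",
            "roulette_threshold": 1e-4,
            "roulette_survival": 0.1,
            "estimator": "path_length",
        },
        "matrix": {
            "morphotypes": list(MORPHOTYPES),
            "irradiance_levels": list(IRRADIANCE_LEVELS),
            "optical_scenarios": [1, 2, 3, 4, 5, 6],
            "pe_sets": list(PE_SETS),
            "structural_variants": list(STRUCTURAL_VARIANTS),
            # structural variants run under the default optical scenario only
            "variant_optical_scenarios": [1],
            "seeds": [0],
            # 2 morphotypes x 2 irradiances x 2 P-E sets x (6 optical
            # scenarios + 5 structural variants under scenario 1)
            "documented_total": 88,
        },
    }


def config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:12]


def load_config(path: str | Path) -> dict:
    cfg = default_config()
    user = yaml.safe_load(Path(path).read_text()) or {}
    for section, values in user.items():
        if section not in cfg:
            cfg[section] = values
        else:
            cfg[section].update(values)
    return cfg


def expand_matrix(config: dict) -> list[ScenarioSpec]:
    """Deterministic full-factorial expansion of the enabled factor levels.

    Optical scenarios cross the default structure; structural variants cross
    the scenarios listed in ``variant_optical_scenarios`` (default: scenario
    1 only).  Specs are de-duplicated preserving order.
    """
    m = config["matrix"]
    for key in ("morphotypes", "irradiance_levels", "optical_scenarios", "pe_sets",
                "structural_variants", "seeds"):
        if not m.get(key):
            raise PipelineError(f"matrix factor {key!r} is empty")
    specs: list[ScenarioSpec] = []
    seen = set()
    variants = list(m["structural_variants"])
    variant_scenarios = m.get("variant_optical_scenarios", [1])
    for morph, level, pe_set, seed in itertools.product(
        m["morphotypes"], m["irradiance_levels"], m["pe_sets"], m["seeds"]
    ):
        combos = [(s, "default") for s in m["optical_scenarios"] if "default" in variants]
        combos += [
            (s, v) for v in variants if v != "default" for s in variant_scenarios
        ]
        for scen, variant in combos:
            spec = ScenarioSpec(
                morphotype=morph,
                irradiance_level=level,
                optical_scenario=int(scen),
                pe_set=pe_set,
                structural_variant=variant,
                replicate_seed=int(seed),
            )
            if spec not in seen:
                seen.add(spec)
                specs.append(spec)
    return specs


def _build_variant(
    morphotype: str,
    variant: str,
    params: dict[str, geo.MorphotypeParams],
    gcfg: dict,
) -> geo.LabelVolume:
    p = params[morphotype]
    other = params[{"shallow": "mesophotic", "mesophotic": "shallow"}[morphotype]]
    kwargs = dict(
        resolution=gcfg["resolution"],
        tile_corallites=gcfg["tile_corallites"],
        water_above=gcfg["water_above"],
        slab_below=gcfg["slab_below"],
        tissue_surface=gcfg.get("tissue_surface", "drape"),
    )
    if variant == "default":
        return geo.build_tile(p, **kwargs)
    if variant.startswith("knockout:"):
        feature = variant.split(":", 1)[1]
        res = kwargs.pop("resolution")
        tiles = kwargs.pop("tile_corallites")
        return geo.knockout_tile(p, feature, resolution=res, tile_corallites=tiles, **kwargs)
    if variant.startswith("exchange:"):
        group = variant.split(":", 1)[1]
        swapped = geo.exchange_traits(p, other, {group})
        return geo.build_tile(swapped, **kwargs)
    raise PipelineError(f"unknown structural variant {variant!r}")


def run_matrix(
    specs: list[ScenarioSpec],
    config: dict | None = None,
    morphotypes: dict[str, geo.MorphotypeParams] | None = None,
    optics: dict[int, OpticalProperties] | None = None,
    pe_sets: dict[str, ps.PEParams] | None = None,
    irradiances: dict[str, float] | None = None,
    out_csv: str | Path | None = None,
) -> pd.DataFrame:
    """Execute the scenario matrix; one result row per spec.

    Per-spec failures are recorded (``status`` column) without aborting the
    batch.  Fluence volumes and geometry tiles are cached across specs.
    If ``out_csv`` is given, rows are streamed to it as they complete.
    """
    config = config or default_config()
    morphotypes = morphotypes or geo.load_default_morphotypes()
    optics = optics or load_optical_scenarios()
    pe_sets = pe_sets or ps.load_default_pe()
    irradiances = irradiances or ps.load_default_irradiances()
    chash = config_hash(config)
    gcfg, tcfg = config["geometry"], config["transport"]

    vol_cache: dict = {}
    metrics_cache: dict = {}
    flu_cache: dict = {}
    rows = []
    for spec in specs:
        row: dict = {**asdict(spec), "config_hash": chash, "status": "ok", "error": ""}
        try:
            gkey = (spec.morphotype, spec.structural_variant)
            if gkey not in vol_cache:
                vol_cache[gkey] = _build_variant(
                    spec.morphotype, spec.structural_variant, morphotypes, gcfg
                )
                metrics_cache[gkey] = geo.surface_metrics(vol_cache[gkey])
            vol = vol_cache[gkey]
            sm = metrics_cache[gkey]

            fkey = (gkey, spec.optical_scenario, spec.replicate_seed)
            if fkey not in flu_cache:
                flu_cache[fkey] = run_mc(
                    vol,
                    optics[spec.optical_scenario],
                    TransportConfig(
                        n_photons=tcfg["n_photons"],
                        seed=spec.replicate_seed,
                        lateral_boundary=tcfg["lateral_boundary"],
                        roulette_threshold=tcfg["roulette_threshold"],
                        roulette_survival=tcfg["roulette_survival"],
                        estimator=tcfg["estimator"],
                    ),
                )
            flu = flu_cache[fkey]

            E0 = irradiances[spec.irradiance_level]
            field = ps.score_volume(flu, vol, pe_sets[spec.pe_set], E0)
            row.update(
                irradiance=E0,
                score=field.summary,
                n_tissue_voxels=field.n_tissue_voxels,
                mean_tissue_phi=mean_tissue_phi(flu, vol),
                surface_area_mm2=sm.surface_area,
                rugosity=sm.rugosity,
                tissue_volume_mm3=sm.tissue_volume,
                escaped_top=flu.escaped_top,
                escaped_other=flu.escaped_other,
                absorbed_tissue=flu.absorbed["tissue"],
                n_photons=flu.n_photons,
            )
        except Exception as exc:  # recorded, batch continues
            logger.exception("scenario failed: %s", spec)
            row["status"] = "error"
            row["error"] = f"{type(exc).__name__}: {exc}"
        rows.append(row)
        if out_csv is not None:
            pd.DataFrame(rows).to_csv(out_csv, index=False)
    return pd.DataFrame(rows)
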