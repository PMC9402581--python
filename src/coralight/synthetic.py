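"""Synthetic morphometric trait tables with the study's sampling design.

Emulates two depth groups of colonies (shallow / mesophotic) with replicate
trait measurements per colony: colony-level values are drawn from a normal
distribution around the group mean truncated at zero (traits are positive
lengths or fractions), and within-colony replicates are multiplicative
lognormal noise with a stated coefficient of variation around the colony
value.  Randomness is counter-based per colony (Philox keyed by
``(seed, colony index)``), so adding colonies never reshuffles earlier ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

TRAITS = (
    "CD", "TH", "SL", "SW", "CH", "SS", "SPL", "SPW", "CSC", "CSM",
    "branch_thickness", "porosity",
)
DEPTH_GROUPS = ("shallow", "mesophotic")


class TraitSpecError(ValueError):
    """Invalid trait-generator specification."""


@dataclass(frozen=True)
class TraitGeneratorSpec:
    """Sampling design for a two-depth-group trait table.

    ``group_means`` maps depth group -> trait -> mean (mm; porosity as a
    fraction).  ``colony_sd`` is the between-colony SD per trait (same
    units); ``replicate_cv`` the within-colony coefficient of variation.
    """

    group_means: dict[str, dict[str, float]]
    colony_sd: dict[str, float]
    replicate_cv: float = 0.05
    n_colonies_per_group: int = 15
    n_replicates: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if set(self.group_means) != set(DEPTH_GROUPS):
            raise TraitSpecError(
                f"group_means must have exactly the groups {DEPTH_GROUPS}, got {sorted(self.group_means)}"
            )
        traits = None
        for g, means in self.group_means.items():
            unknown = set(means) - set(TRAITS)
            if unknown:
                raise TraitSpecError(f"group_means[{g}] has unknown traits {sorted(unknown)}")
            if traits is None:
                traits = set(means)
            elif set(means) != traits:
                raise TraitSpecError("group_means groups must list the same traits")
            for t, m in means.items():
                if m <= 0:
                    raise TraitSpecError(f"group_means[{g}][{t}] must be > 0, got {m}")
        for t, sd in self.colony_sd.items():
            if t not in (traits or set()):
                raise TraitSpecError(f"colony_sd names trait {t!r} absent from group_means")
            if sd < 0:
                raise TraitSpecError(f"colony_sd[{t}] must be >= 0, got {sd}")
        missing = (traits or set()) - set(self.colony_sd)
        if missing:
            raise TraitSpecError(f"colony_sd missing traits {sorted(missing)}")
        if not 0 <= self.replicate_cv < 1:
            raise TraitSpecError(f"replicate_cv must be in [0, 1), got {self.replicate_cv}")
        if self.n_colonies_per_group < 2:
            raise TraitSpecError(f"n_colonies_per_group must be >= 2, got {self.n_colonies_per_group}")
        if self.n_replicates < 1:
            raise TraitSpecError(f"n_replicates must be >= 1, got {self.n_replicates}")

    @property
    def traits(self) -> list[str]:
        return sorted(next(iter(self.group_means.values())))


def default_spec(
    n_colonies_per_group: int = 15,
    n_replicates: int = 10,
    replicate_cv: float = 0.05,
    colony_sd_frac: float = 0.10,
    seed: int = 0,
) -> TraitGeneratorSpec:
    """Study-design spec from the shipped per-morphotype trait-mean fixtures.

    Between-colony SD defaults to 10% of the pooled trait mean.
    """
    path = Path(__file__).parent / "data" / "morphotypes.yaml"
    raw = yaml.safe_load(path.read_text())
    group_means = {g: {t: float(v) for t, v in raw[g].items()} for g in DEPTH_GROUPS}
    pooled = {
        t: 0.5 * (group_means["shallow"][t] + group_means["mesophotic"][t])
        for t in group_means["shallow"]
    }
    colony_sd = {t: colony_sd_frac * m for t, m in pooled.items()}
    return TraitGeneratorSpec(
        group_means=group_means,
        colony_sd=colony_sd,
        replicate_cv=replicate_cv,
        n_colonies_per_group=n_colonies_per_group,
        n_replicates=n_replicates,
        seed=seed,
    )


def _colony_rng(seed: int, stream: int) -> np.random.Generator:
    # Philox is counter-based: keying by (seed, stream) gives independent,
    # order-stable streams regardless of how many colonies are generated.
    return np.random.Generator(np.random.Philox(key=(np.uint64(seed) << np.uint64(32)) + np.uint64(stream)))


def generate_trait_table(spec: TraitGeneratorSpec) -> pd.DataFrame:
    """Generate a tidy trait table per the spec.

    Returns columns ``sample_id, depth_group, trait, replicate_index,
    value, units``; ``n_colonies_per_group * 2`` colonies with
    ``n_replicates`` rows per colony and trait.  Deterministic per seed.
    """
    rows = []
    traits = spec.traits
    for gi, group in enumerate(DEPTH_GROUPS):
        means = spec.group_means[group]
        for c in range(spec.n_colonies_per_group):
            stream = gi * 1_000_000 + c
            rng = _colony_rng(spec.seed, stream)
            sample_id = f"{group[:4]}-{c + 1:02d}"
            for trait in traits:
                mu, sd = means[trait], spec.colony_sd[trait]
                colony_value = _truncated_normal(rng, mu, sd)
                if spec.replicate_cv > 0:
                    sigma = np.sqrt(np.log1p(spec.replicate_cv**2))
                    # lognormal with mean == colony_value
                    reps = colony_value * np.exp(
                        rng.normal(-0.5 * sigma**2, sigma, size=spec.n_replicates)
                    )
                else:
                    reps = np.full(spec.n_replicates, colony_value)
                units = "fraction" if trait == "porosity" else "mm"
                for ri, v in enumerate(reps):
                    rows.append((sample_id, group, trait, ri, float(v), units))
    return pd.DataFrame(
        rows, columns=["sample_id", "depth_group", "trait", "replicate_index", "value", "units"]
    )


def _truncated_normal(rng: np.random.Generator, mu: float, sd: float) -> float:
    """Normal(mu, sd) resampled until positive (mu > 0 guaranteed by spec)."""
    if sd == 0:
        return mu
    for _ in range(1000):
        v = rng.normal(mu, sd)
        if v > 0:
            return v
    raise TraitSpecError(f"truncated normal failed to draw a positive value (mu={mu}, sd={sd})")


def write_trait_csv(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False)


def read_trait_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
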