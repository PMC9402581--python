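"""Statistical surface over morphometric trait tables.

Colonies are the experimental unit throughout: replicate measurements are
collapsed to colony means first, and all inference (permutation tests,
PERMANOVA, ordination, SIMPER, correlations) runs on the colony-mean
matrix.  Group comparisons permute whole colonies across depth groups,
which keeps the colony-level dependence structure intact — the
permutational analogue of treating colony identity as a random effect.

Multivariate analyses standardize traits to zero mean and unit variance
over the pooled colony means and use Euclidean distances.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio.stats.distance import DistanceMatrix
from skbio.stats.ordination import pcoa as _skbio_pcoa

from .synthetic import DEPTH_GROUPS, TRAITS

logger = logging.getLogger(__name__)


class TraitTableError(ValueError):
    """Malformed trait table or invalid analysis request."""


# ---------------------------------------------------------------------------
# table validation and colony means

def validate_trait_table(table: pd.DataFrame) -> pd.DataFrame:
    required = {"sample_id", "depth_group", "trait", "value"}
    missing = required - set(table.columns)
    if missing:
        raise TraitTableError(f"trait table missing columns {sorted(missing)}")
    bad_groups = set(table["depth_group"]) - set(DEPTH_GROUPS)
    if bad_groups:
        raise TraitTableError(f"unknown depth groups {sorted(bad_groups)}")
    bad_traits = set(table["trait"]) - set(TRAITS)
    if bad_traits:
        raise TraitTableError(f"unknown traits {sorted(bad_traits)}")
    if (table["value"] < 0).any():
        raise TraitTableError("trait values must be >= 0")
    poro = table.loc[table["trait"] == "porosity", "value"]
    if (poro > 1).any():
        raise TraitTableError("porosity values must be fractions in [0, 1]")
    n_groups = table.groupby("sample_id")["depth_group"].nunique()
    multi = n_groups[n_groups > 1]
    if len(multi):
        raise TraitTableError(f"samples mapped to multiple depth groups: {list(multi.index)}")
    if "replicate_index" in table.columns:
        dup = table.duplicated(["sample_id", "trait", "replicate_index"])
        if dup.any():
            raise TraitTableError("duplicate (sample_id, trait, replicate_index) keys")
    return table


def colony_means(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Collapse replicates: colonies x traits mean matrix + group labels."""
    validate_trait_table(table)
    wide = table.pivot_table(index="sample_id", columns="trait", values="value", aggfunc="mean")
    groups = table.groupby("sample_id")["depth_group"].first().loc[wide.index]
    return wide, groups


def _standardize(wide: pd.DataFrame) -> pd.DataFrame:
    """Pooled z-scores; zero-variance traits are dropped with a warning."""
    sd = wide.std(ddof=1)
    dropped = sd.index[(sd == 0) | sd.isna()].tolist()
    if dropped:
        logger.warning("dropping zero-variance traits from multivariate analysis: %s", dropped)
    keep = wide.drop(columns=dropped)
    return (keep - keep.mean()) / keep.std(ddof=1)


# ---------------------------------------------------------------------------
# group summaries

def summarize_by_group(table: pd.DataFrame) -> pd.DataFrame:
    """Per-trait group means, SE over colonies, and percent difference.

    ``percent_difference`` is ratio-based, shallow relative to mesophotic:
    ``(mean_shallow / mean_mesophotic - 1) * 100`` (so "+60" reads "60%
    larger in shallow").  SE is NaN for single-colony groups.
    """
    wide, groups = colony_means(table)
    rows = []
    for trait in wide.columns:
        rec: dict[str, float | str] = {"trait": trait}
        for g in DEPTH_GROUPS:
            vals = wide.loc[groups == g, trait].dropna()
            if len(vals) == 0:
                raise TraitTableError(f"depth group {g!r} has no colonies for trait {trait!r}")
            rec[f"mean_{g}"] = vals.mean()
            rec[f"se_{g}"] = vals.std(ddof=1) / math.sqrt(len(vals)) if len(vals) > 1 else np.nan
            rec[f"n_{g}"] = len(vals)
        rec["percent_difference"] = (rec["mean_shallow"] / rec["mean_mesophotic"] - 1.0) * 100.0
        rows.append(rec)
    return pd.DataFrame(rows).set_index("trait")


# ---------------------------------------------------------------------------
# colony-block permutation test (univariate)

def blocked_permutation_test(
    table: pd.DataFrame, trait: str, n_perm: int = 999, seed: int = 0
) -> dict[str, float]:
    """Permutation test of the group mean difference for one trait.

    Whole colonies (not replicates) are permuted across depth groups; the
    statistic is the difference of group means of colony means; the p-value
    uses the add-one correction p = (1 + #{|d*| >= |d|}) / (1 + n_perm).
    """
    if n_perm < 99:
        raise TraitTableError("n_perm must be >= 99")
    wide, groups = colony_means(table)
    if trait not in wide.columns:
        raise TraitTableError(f"trait {trait!r} not present in table")
    vals = wide[trait].to_numpy()
    labels = (groups == "shallow").to_numpy()
    if labels.all() or not labels.any():
        raise TraitTableError("both depth groups are required")
    obs = vals[labels].mean() - vals[~labels].mean()
    rng = np.random.default_rng(seed)
    n_shallow = int(labels.sum())
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(len(vals))
        sel = np.zeros(len(vals), dtype=bool)
        sel[perm[:n_shallow]] = True
        d = vals[sel].mean() - vals[~sel].mean()
        if abs(d) >= abs(obs) - 1e-12:
            count += 1
    return {
        "observed_difference": float(obs),
        "p_value": (1 + count) / (1 + n_perm),
        "n_perm": n_perm,
    }


# ---------------------------------------------------------------------------
# PCoA

@dataclass
class OrdinationResult:
    """Classical-scaling ordination of colony means."""

    coordinates: pd.DataFrame        # samples x axes
    explained_fraction: np.ndarray   # per-axis, non-increasing, sums <= 1
    loadings_proxy: pd.DataFrame     # trait x axis Pearson correlations
    groups: pd.Series
    dropped_traits: list[str] = field(default_factory=list)


def pcoa(table: pd.DataFrame, n_axes: int | None = None) -> OrdinationResult:
    """Principal coordinates analysis on Euclidean distances of z-scored
    colony means (classical scaling; equivalent to PCA scores here)."""
    wide, groups = colony_means(table)
    if len(wide) < 3:
        raise TraitTableError("PCoA requires at least 3 colonies")
    sd = wide.std(ddof=1)
    dropped = sd.index[(sd == 0) | sd.isna()].tolist()
    z = _standardize(wide)
    dm = DistanceMatrix(squareform(pdist(z.to_numpy())), ids=[str(i) for i in z.index])
    res = _skbio_pcoa(dm, number_of_dimensions=n_axes or min(len(wide) - 1, z.shape[1]))
    coords = pd.DataFrame(
        res.samples.to_numpy(), index=z.index,
        columns=[f"PCo{i + 1}" for i in range(res.samples.shape[1])],
    )
    explained = res.proportion_explained.to_numpy()[: coords.shape[1]]
    # loadings proxy: correlation of each (standardized) trait with each axis
    loadings = pd.DataFrame(index=z.columns, columns=coords.columns, dtype=float)
    for t in z.columns:
        for ax in coords.columns:
            cvals = coords[ax]
            if cvals.std(ddof=0) == 0:
                loadings.loc[t, ax] = np.nan
            else:
                loadings.loc[t, ax] = float(np.corrcoef(z[t], cvals)[0, 1])
    return OrdinationResult(
        coordinates=coords,
        explained_fraction=np.clip(explained, 0, None),
        loadings_proxy=loadings,
        groups=groups,
        dropped_traits=dropped,
    )


# ---------------------------------------------------------------------------
# PERMANOVA

def _pseudo_f(d2: np.ndarray, labels: np.ndarray) -> float:
    """Pseudo-F from the squared-distance matrix partition (two groups).

    SS_total = sum_{i<j} d2_ij / n; SS_within sums the same within groups;
    F = (SS_among / (g-1)) / (SS_within / (n-g)).
    """
    n = len(labels)
    iu = np.triu_indices(n, 1)
    ss_t = d2[iu].sum() / n
    ss_w = 0.0
    for g in np.unique(labels):
        idx = np.flatnonzero(labels == g)
        if len(idx) > 1:
            sub = d2[np.ix_(idx, idx)]
            ss_w += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    ss_a = ss_t - ss_w
    n_groups = len(np.unique(labels))
    denom = ss_w / (n - n_groups)
    if denom == 0:
        return 0.0 if ss_a <= 1e-12 else np.inf
    return (ss_a / (n_groups - 1)) / denom


def permanova(
    table: pd.DataFrame, n_perm: int = 999, seed: int = 0, exhaustive: bool = False
) -> dict[str, float]:
    """PERMANOVA of depth group on Euclidean distances of z-scored colony
    means.  Whole colonies are permuted; ``exhaustive=True`` enumerates all
    distinct label assignments instead of sampling (small n only)."""
    wide, groups = colony_means(table)
    labels = (groups == "shallow").to_numpy()
    if labels.all() or not labels.any():
        raise TraitTableError("both depth groups must be non-empty")
    z = _standardize(wide)
    d2 = squareform(pdist(z.to_numpy())) ** 2
    obs = _pseudo_f(d2, labels)
    n = len(labels)
    k = int(labels.sum())
    if exhaustive:
        if math.comb(n, k) > 20000:
            raise TraitTableError("exhaustive enumeration infeasible for this n")
        count = 0
        total = 0
        for comb in itertools.combinations(range(n), k):
            sel = np.zeros(n, dtype=bool)
            sel[list(comb)] = True
            if _pseudo_f(d2, sel) >= obs - 1e-12:
                count += 1
            total += 1
        # the observed assignment is one of the enumerated ones
        p = count / total
        return {"pseudo_F": float(obs), "p_value": p, "n_perm": total, "method": "exhaustive"}
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        sel = np.zeros(n, dtype=bool)
        sel[perm[:k]] = True
        if _pseudo_f(d2, sel) >= obs - 1e-12:
            count += 1
    return {
        "pseudo_F": float(obs),
        "p_value": (1 + count) / (1 + n_perm),
        "n_perm": n_perm,
        "method": "sampled",
    }


# ---------------------------------------------------------------------------
# SIMPER

def simper(table: pd.DataFrame) -> pd.DataFrame:
    """Per-trait percent contribution to between-group dissimilarity.

    Decomposes the average squared Euclidean distance between shallow and
    mesophotic colonies (z-scored traits) into additive per-trait
    components; contributions sum to 100%.
    """
    wide, groups = colony_means(table)
    z = _standardize(wide)
    a = z[(groups == "shallow").to_numpy()].to_numpy()
    b = z[(groups == "mesophotic").to_numpy()].to_numpy()
    if len(a) == 0 or len(b) == 0:
        raise TraitTableError("both depth groups must be non-empty")
    # mean over all between-group pairs of (x_it - x_jt)^2, per trait t
    comp = ((a[:, None, :] - b[None, :, :]) ** 2).mean(axis=(0, 1))
    total = comp.sum()
    if total == 0:
        pct = np.full(len(comp), 100.0 / len(comp))
    else:
        pct = 100.0 * comp / total
    out = pd.DataFrame({"contribution_pct": pct}, index=z.columns)
    return out.sort_values("contribution_pct", ascending=False)


# ---------------------------------------------------------------------------
# correlations

def pearson_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """Trait x trait Pearson correlations over colony means."""
    wide, _ = colony_means(table)
    if len(wide) < 3:
        raise TraitTableError("pearson_matrix requires at least 3 colonies")
    sd = wide.std(ddof=1)
    zero_var = sd.index[(sd == 0) | sd.isna()].tolist()
    if zero_var:
        logger.warning("zero-variance traits yield undefined correlations: %s", zero_var)
    return wide.corr(method="pearson")
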