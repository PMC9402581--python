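"""Morphometric statistics: summaries, permutation tests, ordination."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from coralight import morphometrics as mm
from coralight import synthetic
from coralight.morphometrics import TraitTableError


def make_table(shallow_cols, meso_cols, traits):
    """Build a replicate-free trait table from per-colony trait values."""
    rows = []
    for group, cols in (("shallow", shallow_cols), ("mesophotic", meso_cols)):
        for ci, colony in enumerate(cols):
            for trait, value in zip(traits, colony):
                rows.append((f"{group[:4]}-{ci}", group, trait, 0, value, "mm"))
    return pd.DataFrame(rows, columns=["sample_id", "depth_group", "trait",
                                       "replicate_index", "value", "units"])


@pytest.fixture(scope="module")
def fixture_table():
    return synthetic.generate_trait_table(synthetic.default_spec(seed=11))


# -- summaries ---------------------------------------------------------------

def test_percent_difference_matches_printed_cd_effect():
    # colony means 1.0 vs 0.625 -> shallow CD is 60% larger
    t = make_table([[1.0]] * 4, [[0.625]] * 4, ["CD"])
    out = mm.summarize_by_group(t)
    assert out.loc["CD", "percent_difference"] == pytest.approx(60.0)


def test_single_colony_group_reports_nan_se():
    t = make_table([[1.0]], [[0.6]], ["CD"])
    out = mm.summarize_by_group(t)
    assert math.isnan(out.loc["CD", "se_shallow"])
    assert out.loc["CD", "mean_shallow"] == 1.0


def test_swapping_group_labels_flips_difference_sign():
    t = make_table([[1.0]] * 3, [[0.7]] * 3, ["CD"])
    swapped = t.copy()
    swapped["depth_group"] = swapped["depth_group"].map(
        {"shallow": "mesophotic", "mesophotic": "shallow"})
    d1 = mm.summarize_by_group(t).loc["CD", "percent_difference"]
    d2 = mm.summarize_by_group(swapped).loc["CD", "percent_difference"]
    assert d1 > 0 > d2


def test_empty_group_raises_naming_group():
    t = make_table([[1.0]] * 3, [[0.7]] * 3, ["CD"])
    t = t[t.depth_group == "shallow"]
    with pytest.raises(TraitTableError, match="mesophotic"):
        mm.summarize_by_group(t)


# -- blocked permutation test ------------------------------------------------

def test_constant_data_gives_zero_difference_p_one():
    t = make_table([[2.0]] * 5, [[2.0]] * 5, ["CD"])
    res = mm.blocked_permutation_test(t, "CD", n_perm=199, seed=0)
    assert res["observed_difference"] == 0.0
    assert res["p_value"] == 1.0


def test_missing_trait_raises():
    t = make_table([[1.0]] * 3, [[0.7]] * 3, ["CD"])
    with pytest.raises(TraitTableError, match="TH"):
        mm.blocked_permutation_test(t, "TH")


def test_rescaling_a_trait_leaves_p_value_unchanged():
    rng = np.random.default_rng(4)
    sh = [[v] for v in rng.normal(1.0, 0.1, 8)]
    me = [[v] for v in rng.normal(0.8, 0.1, 8)]
    t = make_table(sh, me, ["CD"])
    t2 = t.copy()
    t2["value"] *= 3.7
    r1 = mm.blocked_permutation_test(t, "CD", n_perm=299, seed=5)
    r2 = mm.blocked_permutation_test(t2, "CD", n_perm=299, seed=5)
    assert r1["p_value"] == r2["p_value"]


def test_null_rejection_rate_is_nominal_smoke():
    # light version of the calibration check (full version in acceptance)
    rejections = 0
    n_seeds = 60
    for seed in range(n_seeds):
        rng = np.random.default_rng(1000 + seed)
        sh = [[v] for v in rng.normal(1.0, 0.1, 10)]
        me = [[v] for v in rng.normal(1.0, 0.1, 10)]
        t = make_table(sh, me, ["CD"])
        if mm.blocked_permutation_test(t, "CD", n_perm=199, seed=seed)["p_value"] < 0.05:
            rejections += 1
    assert rejections / n_seeds < 0.14


# -- PCoA --------------------------------------------------------------------

def test_pcoa_scores_match_pca_of_standardized_data(fixture_table):
    res = mm.pcoa(fixture_table)
    wide, _ = mm.colony_means(fixture_table)
    z = (wide - wide.mean()) / wide.std(ddof=1)
    z = z.dropna(axis=1)
    # classical scaling on Euclidean distances == PCA scores up to sign
    u, s, vt = np.linalg.svd(z.to_numpy() - z.to_numpy().mean(0), full_matrices=False)
    pca_scores = u * s
    k = min(3, res.coordinates.shape[1])
    for i in range(k):
        a, b = res.coordinates.iloc[:, i].to_numpy(), pca_scores[:, i]
        assert min(np.abs(a - b).max(), np.abs(a + b).max()) < 1e-6 * max(1, np.abs(b).max())
    fr = res.explained_fraction
    assert np.all(np.diff(fr) <= 1e-12)
    assert fr.sum() <= 1 + 1e-9


def test_pcoa_separated_clouds_put_all_variance_on_axis1():
    # group separation >> within-group noise on both (standardized) traits
    rng = np.random.default_rng(0)
    sh = (np.array([10.0, 10.0]) + rng.normal(0, 0.05, (4, 2))).tolist()
    me = (np.array([1.0, 1.0]) + rng.normal(0, 0.05, (4, 2))).tolist()
    t = make_table(sh, me, ["CD", "TH"])
    res = mm.pcoa(t)
    assert res.explained_fraction[0] > 0.95


def test_pcoa_drops_constant_trait_with_warning(caplog):
    sh = [[1.0 + 0.1 * i, 5.0] for i in range(3)]
    me = [[0.6 + 0.1 * i, 5.0] for i in range(3)]
    t = make_table(sh, me, ["CD", "TH"])
    with caplog.at_level("WARNING"):
        res = mm.pcoa(t)
    assert res.dropped_traits == ["TH"]
    assert "TH" in caplog.text


def test_pcoa_distances_reconstructed(fixture_table):
    res = mm.pcoa(fixture_table, n_axes=None)
    wide, _ = mm.colony_means(fixture_table)
    z = (wide - wide.mean()) / wide.std(ddof=1)
    want = pdist(z.to_numpy())
    got = pdist(res.coordinates.to_numpy())
    assert np.allclose(got, want, rtol=1e-6, atol=1e-8)


def test_fixture_design_axes_capture_majority_of_variance(fixture_table):
    res = mm.pcoa(fixture_table)
    assert res.explained_fraction[:2].sum() > 0.5


# -- PERMANOVA ---------------------------------------------------------------

def _anova_pseudo_f(z, labels):
    """Independent oracle: pseudo-F from coordinate sums of squares."""
    grand = z.mean(axis=0)
    ss_t = ((z - grand) ** 2).sum()
    ss_w = 0.0
    for g in (True, False):
        sub = z[labels == g]
        ss_w += ((sub - sub.mean(axis=0)) ** 2).sum()
    n, k = len(z), 2
    return ((ss_t - ss_w) / (k - 1)) / (ss_w / (n - k))


def test_permanova_matches_anova_decomposition_and_exhaustive_oracle():
    # 4 + 4 colonies, 2 traits: compare against coordinate-space ANOVA and
    # full enumeration of the 70 label assignments
    rng = np.random.default_rng(9)
    sh = rng.normal([1.0, 0.5], 0.08, size=(4, 2))
    me = rng.normal([0.7, 0.8], 0.08, size=(4, 2))
    t = make_table(sh.tolist(), me.tolist(), ["CD", "TH"])
    res = mm.permanova(t, exhaustive=True)

    wide, groups = mm.colony_means(t)
    z = ((wide - wide.mean()) / wide.std(ddof=1)).to_numpy()
    labels = (groups == "shallow").to_numpy()
    f_oracle = _anova_pseudo_f(z, labels)
    assert res["pseudo_F"] == pytest.approx(f_oracle, rel=1e-9)

    count = 0
    combos = list(itertools.combinations(range(8), 4))
    for comb in combos:
        sel = np.zeros(8, dtype=bool)
        sel[list(comb)] = True
        if _anova_pseudo_f(z, sel) >= f_oracle - 1e-12:
            count += 1
    assert res["p_value"] == pytest.approx(count / len(combos))


def test_permanova_agrees_with_skbio():
    pytest.importorskip("skbio")
    from skbio.stats.distance import DistanceMatrix, permanova as sk_permanova

    table = synthetic.generate_trait_table(synthetic.default_spec(seed=21))
    res = mm.permanova(table, n_perm=99, seed=0)
    wide, groups = mm.colony_means(table)
    z = (wide - wide.mean()) / wide.std(ddof=1)
    dm = DistanceMatrix(squareform(pdist(z.to_numpy())), ids=[str(i) for i in z.index])
    sk = sk_permanova(dm, grouping=groups.to_numpy(), permutations=99)
    assert res["pseudo_F"] == pytest.approx(sk["test statistic"], rel=1e-9)


def test_permanova_identical_groups_not_significant():
    vals = [[1.0, 0.4], [1.1, 0.5], [0.9, 0.6], [1.05, 0.45]]
    t = make_table(vals, vals, ["CD", "TH"])
    res = mm.permanova(t, exhaustive=True)
    assert res["p_value"] > 0.5


def test_permanova_empty_group_raises():
    t = make_table([[1.0], [1.1], [0.9]], [[0.6], [0.7], [0.65]], ["CD"])
    t = t[t.depth_group == "shallow"]
    with pytest.raises(TraitTableError):
        mm.permanova(t)


# -- SIMPER ------------------------------------------------------------------

def test_simper_single_differing_trait_contributes_everything():
    # the only varying trait carries the whole between-group dissimilarity
    # (the constant trait is dropped by standardization)
    sh = [[1.0 + 0.01 * i, 5.0] for i in range(4)]
    me = [[0.5 + 0.01 * i, 5.0] for i in range(4)]
    t = make_table(sh, me, ["CD", "TH"])
    out = mm.simper(t)
    assert out.loc["CD", "contribution_pct"] == pytest.approx(100.0)
    assert out["contribution_pct"].sum() == pytest.approx(100.0)


def test_simper_symmetric_effects_split_evenly():
    rng = np.random.default_rng(2)
    sh = np.column_stack([rng.normal(1.0, 0.05, 40), rng.normal(1.0, 0.05, 40)])
    me = np.column_stack([rng.normal(0.8, 0.05, 40), rng.normal(0.8, 0.05, 40)])
    t = make_table(sh.tolist(), me.tolist(), ["CD", "TH"])
    out = mm.simper(t)
    assert out["contribution_pct"].max() < 58.0  # ~50/50 within noise


def test_simper_fixture_effects_rank_high(fixture_table):
    out = mm.simper(fixture_table)
    ranks = {t: i for i, t in enumerate(out.index)}
    n = len(out)
    for trait in ("CD", "TH", "CSM"):
        assert ranks[trait] < n / 2, f"{trait} ranked {ranks[trait]} of {n}"


# -- Pearson -----------------------------------------------------------------

def test_duplicated_trait_correlates_exactly():
    rng = np.random.default_rng(3)
    vals = rng.normal(1.0, 0.2, 6)
    t = make_table([[v, v] for v in vals[:3]], [[v, v] for v in vals[3:]], ["CD", "TH"])
    corr = mm.pearson_matrix(t)
    assert corr.loc["CD", "TH"] == pytest.approx(1.0)
    assert np.allclose(np.diag(corr), 1.0)


def test_negative_affine_relation_gives_minus_one():
    rng = np.random.default_rng(3)
    vals = rng.normal(1.0, 0.2, 8)
    t = make_table([[v, 2.0 - 0.5 * v] for v in vals[:4]],
                   [[v, 2.0 - 0.5 * v] for v in vals[4:]], ["CD", "CSM"])
    corr = mm.pearson_matrix(t)
    assert corr.loc["CD", "CSM"] == pytest.approx(-1.0)


def test_fixture_sign_pattern_matches_study(fixture_table):
    # CD, TH, SPL co-vary positively across the depth contrast; CSM opposes
    corr = mm.pearson_matrix(fixture_table)
    assert corr.loc["CD", "TH"] > 0
    assert corr.loc["CD", "SPL"] > 0
    assert corr.loc["CD", "CSM"] < 0
    assert ((corr.to_numpy() <= 1 + 1e-12) & (corr.to_numpy() >= -1 - 1e-12)).all()
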