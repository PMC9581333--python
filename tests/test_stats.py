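"""Statistics: fences, normality, RM-ANOVA, Tukey HSD, Wilcoxon, ratios, ranking."""
import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats as sst

from scratchkit.cohort import CohortSpec, load_group_means, simulate_cohort
from scratchkit.stats import (
    anova_with_posthoc,
    apply_outlier_fences,
    build_dose_response,
    compact_letter_display,
    dose_response_from_anchors,
    normality_summary,
    peak_ratio_report,
    rank_pruritogens,
    remove_outliers,
    rm_anova,
    tukey_hsd,
    wilcoxon_rank_sum,
)
from scratchkit.stats import test_normality as normality_test

# ------------------------------------------------------------ outlier fences


def test_constant_values_keep_everything():
    kept, removed = remove_outliers([5.0] * 6)
    assert kept.size == 6 and removed.size == 0


def test_fence_arithmetic():
    values = [10, 12, 11, 13, 12, 500]
    x = np.asarray(values, float)
    q1, q3 = np.quantile(x, [0.25, 0.75])
    lo, hi = q1 - 2.2 * (q3 - q1), q3 + 2.2 * (q3 - q1)
    kept, removed = remove_outliers(values)
    assert set(removed) == {v for v in values if not lo <= v <= hi} == {500}
    assert kept.size == 5


def test_single_pass_idempotence():
    kept, _ = remove_outliers([10, 12, 11, 13, 12, 500])
    kept2, removed2 = remove_outliers(kept)
    assert removed2.size == 0 and np.array_equal(np.sort(kept), np.sort(kept2))


def test_too_few_values_rejected():
    with pytest.raises(ValueError, match="too few"):
        remove_outliers([1.0, 2.0, 3.0])


@given(st.lists(st.floats(min_value=-1e6, max_value=1e6), min_size=4, max_size=50))
def test_removal_never_widens_kept_range(values):
    x = np.asarray(values, float)
    kept, removed = remove_outliers(x)
    assert kept.size >= 1
    assert kept.min() >= x.min() and kept.max() <= x.max()
    # one-pass semantics: a second pass on the kept values removes nothing
    if kept.size >= 4 and removed.size == 0:
        assert remove_outliers(kept)[1].size == 0


def test_hinge_convention_available():
    kept, removed = remove_outliers([10, 12, 11, 13, 12, 500], quantile_method="hinges")
    assert 500 in removed


def test_apply_fences_per_cell():
    rng = np.random.default_rng(0)
    rows = []
    for prur in ("a", "b"):
        for dose in (1.0, 3.0):
            for animal in range(8):
                rows.append({"strain": "C57", "pruritogen": prur, "dose_fold": dose,
                             "animal_id": f"{prur}{animal}",
                             "bouts": 100.0 + rng.normal(0, 5)})
    df = pd.DataFrame(rows)
    df.loc[3, "bouts"] = 1_000_000.0  # one gross outlier in cell a/1.0
    kept = apply_outlier_fences(df)
    assert 3 not in kept.index
    assert len(kept) == len(df) - 1


# ---------------------------------------------------------------- normality


def test_normality_calibration():
    """A valid 5% test keeps p > 0.05 for most truly normal samples."""
    rng = np.random.default_rng(1)
    hits = sum(normality_test(rng.normal(size=500)).p > 0.05 for _ in range(100))
    assert hits >= 90


def test_normality_detects_two_point_distribution():
    rng = np.random.default_rng(1)
    x = rng.choice([0.0, 1.0], size=500)
    assert normality_test(x, "shapiro_wilk").p < 0.01
    assert normality_test(x, "ks_lilliefors").p < 0.01


def test_constant_sample_rejected():
    with pytest.raises(ValueError, match="degenerate"):
        normality_test([3.0] * 10)


def test_normality_summary_printed_convention():
    s = normality_summary(47, 53)
    assert s.percent == pytest.approx(100 * 47 / 53)
    assert s.percent_printed == 88.67


# ------------------------------------------------------------------ RM-ANOVA


def _rm_oracle(wide: np.ndarray):
    """Independent sums-of-squares decomposition via explicit cell loops."""
    n, k = wide.shape
    grand = wide.mean()
    ss_sub = sum(k * (wide[i].mean() - grand) ** 2 for i in range(n))
    ss_lvl = sum(n * (wide[:, j].mean() - grand) ** 2 for j in range(k))
    ss_tot = sum((wide[i, j] - grand) ** 2 for i in range(n) for j in range(k))
    ss_err = ss_tot - ss_sub - ss_lvl
    F = (ss_lvl / (k - 1)) / (ss_err / ((n - 1) * (k - 1)))
    return F, (k - 1), (n - 1) * (k - 1)


def _long(wide: np.ndarray) -> pd.DataFrame:
    n, k = wide.shape
    return pd.DataFrame(
        [{"animal_id": i, "dose_fold": j, "bouts": wide[i, j]} for i in range(n) for j in range(k)]
    )


def test_two_levels_equal_squared_paired_t():
    rng = np.random.default_rng(0)
    wide = rng.normal(size=(8, 1)) + np.array([[0.0, 1.0]]) + rng.normal(size=(8, 2))
    res = rm_anova(_long(wide))
    t, p = sst.ttest_rel(wide[:, 0], wide[:, 1])
    assert res.effect("dose_fold")["F"] == pytest.approx(t**2, rel=1e-8)
    assert res.effect("dose_fold")["p"] == pytest.approx(p, rel=1e-8)


def test_no_within_effect_gives_zero_f():
    offsets = np.arange(6.0)[:, None]
    wide = np.tile([10.0, 10.0, 10.0, 10.0], (6, 1)) + offsets
    res = rm_anova(_long(wide))
    assert res.effect("dose_fold")["F"] == pytest.approx(0.0, abs=1e-12)


def test_rm_anova_matches_ss_oracle():
    rng = np.random.default_rng(42)
    effect = np.array([0.0, 1.0, 2.0, 3.0])
    wide = rng.normal(size=(8, 1)) + effect + rng.normal(size=(8, 4))
    res = rm_anova(_long(wide))
    F, df1, df2 = _rm_oracle(wide)
    assert res.effect("dose_fold")["F"] == pytest.approx(F, rel=1e-8)
    assert (res.effect("dose_fold")["df"], res.df_error) == (df1, df2)


def test_rm_anova_cross_checked_against_pingouin(default_cohort):
    pg = pytest.importorskip("pingouin")
    sub = default_cohort[(default_cohort.strain == "C57") & (default_cohort.pruritogen == "LPA")]
    res = rm_anova(sub)
    ref = pg.rm_anova(data=sub, dv="bouts", within="dose_fold", subject="animal_id")
    assert res.effect("dose_fold")["F"] == pytest.approx(ref["F"].iloc[0], rel=1e-8)
    assert res.effect("dose_fold")["p"] == pytest.approx(ref["p_unc"].iloc[0], rel=1e-6)


def test_mixed_design_cross_checked_against_pingouin(default_cohort):
    pg = pytest.importorskip("pingouin")
    sub = default_cohort[default_cohort.pruritogen == "endothelin"]
    res = rm_anova(sub, between="strain")
    ref = pg.mixed_anova(data=sub, dv="bouts", within="dose_fold",
                         subject="animal_id", between="strain")
    ref = ref.set_index("Source")
    assert res.effect("strain")["F"] == pytest.approx(ref.loc["strain", "F"], rel=1e-8)
    assert res.effect("dose_fold")["F"] == pytest.approx(ref.loc["dose_fold", "F"], rel=1e-8)
    assert res.effect("dose_fold:strain")["F"] == pytest.approx(
        ref.loc["Interaction", "F"], rel=1e-8
    )


def test_incomplete_subjects_dropped():
    wide = np.arange(12.0).reshape(4, 3) + np.random.default_rng(0).normal(size=(4, 3))
    df = _long(wide)
    df = df.drop(df.index[-1])  # subject 3 misses one level
    res = rm_anova(df)
    assert res.n_subjects == 3


def test_underpowered_design_rejected():
    with pytest.raises(ValueError, match="underpowered"):
        rm_anova(_long(np.ones((1, 4))))


def test_gg_epsilon_in_range():
    rng = np.random.default_rng(5)
    wide = rng.normal(size=(10, 4)).cumsum(axis=1)  # strongly non-spherical
    res = rm_anova(_long(wide), gg_correction=True)
    eps = res.table["gg_eps"].iloc[0]
    assert 1.0 / 3.0 <= eps <= 1.0
    plain = rm_anova(_long(wide))
    assert res.effect("dose_fold")["p"] >= plain.effect("dose_fold")["p"]


# ---------------------------------------------------------------- Tukey HSD


def test_identical_means_share_letter():
    means = {"a": 10.0, "b": 10.0}
    table, letters = tukey_hsd(means, {"a": 6, "b": 6}, ms_error=4.0, df_error=10)
    assert table["p_adj"].iloc[0] == pytest.approx(1.0)
    assert letters["a"] == letters["b"]


def test_two_levels_tukey_equals_unadjusted_t():
    rng = np.random.default_rng(1)
    wide = rng.normal(size=(8, 1)) + np.array([[0.0, 0.8]]) + rng.normal(size=(8, 2))
    res = anova_with_posthoc(_long(wide))
    # with k = 2 the studentized range collapses to the paired comparison
    assert res.posthoc["p_adj"].iloc[0] == pytest.approx(res.effect("dose_fold")["p"], rel=1e-6)


def test_separated_means_all_distinct_letters():
    means = {lv: 100.0 * lv for lv in range(4)}
    ns = {lv: 8 for lv in range(4)}
    table, letters = tukey_hsd(means, ns, ms_error=1e-6, df_error=21)
    assert (table["p_adj"] < 1e-6).all()
    assert len(set(letters.values())) == 4


def test_letter_display_exhaustive_four_levels():
    """Compare the greedy letter display with an exhaustive set cover on
    every significance pattern of 4 levels."""
    levels = list(range(4))
    pairs = list(itertools.combinations(levels, 2))
    for mask in range(2 ** len(pairs)):
        nonsig = [p for i, p in enumerate(pairs) if mask >> i & 1]
        letters = compact_letter_display(levels, nonsig)
        nonsig_set = {frozenset(p) for p in nonsig}
        for a, b in pairs:
            share = bool(set(letters[a]) & set(letters[b]))
            if frozenset((a, b)) not in nonsig_set:
                assert not share, (nonsig, letters)
        # every non-significant pair must share a letter when the pattern is
        # realizable as cliques (insert-absorb guarantees pair coverage)
        for a, b in nonsig:
            assert set(letters[a]) & set(letters[b]), (nonsig, letters)


def test_invalid_error_term():
    with pytest.raises(ValueError, match="invalid error term"):
        tukey_hsd({"a": 1.0, "b": 2.0}, {"a": 3, "b": 3}, ms_error=0.0, df_error=4)


# ------------------------------------------------------------------ Wilcoxon


def test_identical_samples_p_one():
    w, p = wilcoxon_rank_sum([1, 2, 3], [1, 2, 3])
    assert p == pytest.approx(1.0)


def test_most_extreme_arrangement_doubled():
    w, p = wilcoxon_rank_sum([1, 2, 3], [10, 11, 12])
    assert w == 6.0
    assert p == pytest.approx(0.1)  # 2/20 arrangements


def test_exact_branch_matches_scipy_enumeration():
    rng = np.random.default_rng(0)
    for na in range(2, 6):
        for nb in range(na, 11 - na):
            a = rng.normal(size=na)
            b = rng.normal(size=nb)
            _, p = wilcoxon_rank_sum(a, b)
            ref = sst.mannwhitneyu(a, b, method="exact", alternative="two-sided").pvalue
            assert p == pytest.approx(ref, abs=1e-12)


def test_normal_approximation_close_to_exact_at_7v7():
    from scratchkit.stats import _normal_approx_p

    rng = np.random.default_rng(0)
    diffs = []
    for _ in range(50):
        a = rng.normal(size=7)
        b = rng.normal(0.5, 1.0, size=7)
        _, p_exact = wilcoxon_rank_sum(a, b)
        ranks = sst.rankdata(np.concatenate([a, b]))
        diffs.append(abs(p_exact - _normal_approx_p(ranks, 7)))
    assert max(diffs) < 0.02
    assert np.mean(diffs) < 0.01


def test_empty_sample_rejected():
    with pytest.raises(ValueError):
        wilcoxon_rank_sum([], [1.0])


# ------------------------------------------------- dose-response and ratios


def test_dose_response_cells(default_cohort):
    table = build_dose_response(default_cohort)
    assert len(table) == 2 * 7 * 4
    assert (table["n"] == 8).all()
    peaks = table[table["is_peak"]]
    assert len(peaks) == 14  # one per strain x pruritogen


def test_peak_tie_resolves_to_lower_dose():
    df = pd.DataFrame(
        {"strain": "C57", "pruritogen": "x", "dose_fold": [0.3, 1, 3, 10] * 3,
         "animal_id": np.repeat([1, 2, 3], 4), "bouts": 100}
    )
    table = build_dose_response(df)
    assert table.loc[table["is_peak"], "dose_fold"].iloc[0] == 0.3


def test_single_animal_cell_flagged():
    df = pd.DataFrame(
        {"strain": "C57", "pruritogen": "x", "dose_fold": [1.0], "animal_id": [1], "bouts": [50]}
    )
    table = build_dose_response(df)
    assert not table["sem_defined"].iloc[0]
    assert np.isnan(table["sem"].iloc[0])


def test_anchor_table_peaks():
    mt = load_group_means()["strains"]
    c57 = dose_response_from_anchors(mt, "C57")
    peak = c57[(c57.pruritogen == "endothelin") & c57.is_peak]
    assert peak["dose_fold"].iloc[0] == 10.0
    assert peak["mean"].iloc[0] == 1633.0


def test_peak_ratio_self_is_100_percent():
    mt = load_group_means()["strains"]
    c57 = dose_response_from_anchors(mt, "C57")
    rep = peak_ratio_report(c57, c57)
    assert (rep["percent"] == 100).all()
    assert (rep["fold"] == 1.0).all()


def test_percent_fold_duality():
    mt = load_group_means()["strains"]
    rep = peak_ratio_report(
        dose_response_from_anchors(mt, "C57"), dose_response_from_anchors(mt, "C3H")
    )
    assert np.allclose(rep["percent_raw"] * rep["fold_raw"], 100.0)


def test_zero_peak_rejected():
    df = pd.DataFrame({"pruritogen": ["x"], "mean": [0.0]})
    with pytest.raises(ValueError, match="undefined ratio"):
        peak_ratio_report(df, df)


# -------------------------------------------------------------------- ranking


def test_dominant_pruritogen_ranks_first_with_unique_letter():
    rng = np.random.default_rng(0)
    rows = []
    for p_i, (prur, mean) in enumerate([("big", 1000.0), ("mid", 50.0), ("small", 45.0)]):
        for animal in range(8):
            for dose in (0.3, 1.0, 3.0, 10.0):
                rows.append({"animal_id": f"{prur}{animal}", "pruritogen": prur,
                             "dose_fold": dose, "bouts": mean + rng.normal(0, 5)})
    ranking = rank_pruritogens(pd.DataFrame(rows))
    assert ranking["pruritogen"].iloc[0] == "big"
    big_letters = set(ranking.set_index("pruritogen").loc["big", "letters"])
    others = ranking[ranking.pruritogen != "big"]["letters"]
    assert all(not big_letters & set(l) for l in others)


def test_exchangeable_pruritogens_share_letter():
    rng = np.random.default_rng(1)
    rows = []
    for prur in ("a", "b"):
        for animal in range(8):
            base = rng.normal(100, 10)
            for dose in (1.0, 3.0):
                rows.append({"animal_id": f"{prur}{animal}", "pruritogen": prur,
                             "dose_fold": dose, "bouts": base + rng.normal(0, 5)})
    ranking = rank_pruritogens(pd.DataFrame(rows))
    assert set(ranking["letters"].iloc[0]) & set(ranking["letters"].iloc[1])


def test_default_c57_ranking_endothelin_first(default_cohort):
    ranking = rank_pruritogens(default_cohort[default_cohort.strain == "C57"])
    assert ranking["pruritogen"].iloc[0] == "endothelin"
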