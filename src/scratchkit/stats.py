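"""Dose-response statistics for scratch-bout cohorts.

Implements the full downstream workflow used on the strain x pruritogen x
dose design: Tukey-fence outlier removal (k = 2.2 x IQR), normality
screening (Shapiro-Wilk or Lilliefors-corrected Kolmogorov-Smirnov),
classical repeated-measures ANOVA with dose as the within-subject factor
(optionally strain between subjects), Tukey HSD post hoc with a compact
letter display, an exact/asymptotic Wilcoxon rank-sum fallback for
non-normal groups, per-cell dose-response summaries, cross-strain peak
ratios and a potency ranking.
"""
from __future__ import annotations

import itertools
import math
import string
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sst
from statsmodels.stats.diagnostic import lilliefors

__all__ = [
    "remove_outliers",
    "apply_outlier_fences",
    "test_normality",
    "NormalityResult",
    "normality_summary",
    "NormalitySummary",
    "rm_anova",
    "AnovaResult",
    "tukey_hsd",
    "compact_letter_display",
    "wilcoxon_rank_sum",
    "build_dose_response",
    "dose_response_from_anchors",
    "peak_ratio_report",
    "rank_pruritogens",
]

ALPHA = 0.05


# ---------------------------------------------------------------------------
# outlier fences


def remove_outliers(
    values, k: float = 2.2, quantile_method: str = "linear"
) -> tuple[np.ndarray, np.ndarray]:
    """Single-pass Tukey fences at ``k`` x IQR; returns ``(kept, removed)``.

    ``quantile_method`` is either ``"linear"`` (interpolation type 7) or
    ``"hinges"`` (Tukey hinges: medians of the lower/upper half including
    the overall median at odd n).
    """
    x = np.asarray(values, float)
    if x.size < 4:
        raise ValueError("too few for fences: need >= 4 values")
    if quantile_method == "linear":
        q1, q3 = np.quantile(x, [0.25, 0.75])
    elif quantile_method == "hinges":
        s = np.sort(x)
        half = (s.size + 1) // 2
        q1 = np.median(s[:half])
        q3 = np.median(s[-half:])
    else:
        raise ValueError(f"unknown quantile_method {quantile_method!r}")
    iqr = q3 - q1
    lo, hi = q1 - k * iqr, q3 + k * iqr
    keep = (x >= lo) & (x <= hi)
    return x[keep], x[~keep]


def apply_outlier_fences(
    cohort: pd.DataFrame,
    value_col: str = "bouts",
    group_cols: tuple[str, ...] = ("strain", "pruritogen", "dose_fold"),
    k: float = 2.2,
    quantile_method: str = "linear",
) -> pd.DataFrame:
    """Fence each strain x pruritogen x dose cell; groups with n < 4 pass through."""
    keep_idx = []
    for _, g in cohort.groupby(list(group_cols), sort=False):
        if len(g) < 4:
            keep_idx.extend(g.index)
            continue
        x = g[value_col].to_numpy(float)
        kept, _ = remove_outliers(x, k, quantile_method)
        lo, hi = kept.min(), kept.max()
        mask = (x >= lo) & (x <= hi)
        keep_idx.extend(g.index[mask])
    return cohort.loc[sorted(keep_idx)]


# ---------------------------------------------------------------------------
# normality


@dataclass
class NormalityResult:
    statistic: float
    p: float
    method: str


def test_normality(values, method: str = "shapiro_wilk") -> NormalityResult:
    """Shapiro-Wilk (default) or Lilliefors-corrected KS test of normality."""
    x = np.asarray(values, float)
    if x.size < 4:
        raise ValueError("need >= 4 values")
    if np.all(x == x[0]):
        raise ValueError("degenerate sample: constant input")
    if method == "shapiro_wilk":
        stat, p = sst.shapiro(x)
    elif method == "ks_lilliefors":
        stat, p = lilliefors(x, dist="norm")
    else:
        raise ValueError(f"unknown method {method!r}")
    return NormalityResult(float(stat), float(p), method)


@dataclass
class NormalitySummary:
    n_normal: int
    n_total: int

    @property
    def fraction(self) -> float:
        return self.n_normal / self.n_total

    @property
    def percent(self) -> float:
        return 100.0 * self.fraction

    @property
    def percent_printed(self) -> float:
        """Percentage truncated to two decimals (the reporting convention)."""
        return math.floor(self.percent * 100.0) / 100.0


def normality_summary(n_normal: int, n_total: int) -> NormalitySummary:
    if not 0 <= n_normal <= n_total or n_total <= 0:
        raise ValueError("need 0 <= n_normal <= n_total, n_total > 0")
    return NormalitySummary(n_normal, n_total)


def screen_groups(
    cohort: pd.DataFrame,
    value_col: str = "bouts",
    group_cols: tuple[str, ...] = ("strain", "pruritogen", "dose_fold"),
    method: str = "shapiro_wilk",
    alpha: float = ALPHA,
) -> tuple[pd.DataFrame, NormalitySummary]:
    """Normality test per group cell; returns the per-group table and tally."""
    rows = []
    for keys, g in cohort.groupby(list(group_cols), sort=False):
        x = g[value_col].to_numpy(float)
        if x.size < 4 or np.all(x == x[0]):
            continue
        r = test_normality(x, method)
        rows.append(dict(zip(group_cols, keys)) | {"statistic": r.statistic, "p": r.p})
    table = pd.DataFrame(rows)
    n_normal = int((table["p"] > alpha).sum()) if len(table) else 0
    return table, normality_summary(n_normal, max(len(table), 1))


# ---------------------------------------------------------------------------
# repeated-measures ANOVA


@dataclass
class AnovaResult:
    """Classical univariate RM-ANOVA decomposition.

    ``table`` has one row per effect (ss, df, ms, F, p); ``ms_error`` /
    ``df_error`` are the within-subject residual terms used by Tukey HSD.
    ``posthoc`` and ``letters`` are attached by :func:`tukey_hsd`.
    """

    table: pd.DataFrame
    ms_error: float
    df_error: float
    level_means: dict
    level_ns: dict
    n_subjects: int
    posthoc: pd.DataFrame | None = None
    letters: dict | None = None

    def effect(self, name: str) -> pd.Series:
        return self.table.set_index("effect").loc[name]


def _gg_epsilon(Y: np.ndarray) -> float:
    """Greenhouse-Geisser sphericity epsilon from the sample covariance."""
    S = np.cov(Y, rowvar=False)
    k = S.shape[0]
    row = S.mean(axis=0, keepdims=True)
    dc = S - row - row.T + S.mean()
    num = np.trace(dc) ** 2
    den = (k - 1) * np.sum(dc * dc)
    return float(num / den) if den > 0 else 1.0


def rm_anova(
    data: pd.DataFrame,
    dv: str = "bouts",
    within: str = "dose_fold",
    subject: str = "animal_id",
    between: str | None = None,
    gg_correction: bool = False,
) -> AnovaResult:
    """Repeated-measures ANOVA on a long-format table, complete cases only.

    Subjects missing any within-level are dropped.  With ``between`` given
    the classical split-plot (mixed) partition is used; group sizes should
    be balanced for the interaction term to be exact.  No sphericity
    correction is applied unless ``gg_correction`` is set.
    """
    wide = data.pivot_table(index=subject, columns=within, values=dv, aggfunc="mean")
    wide = wide.dropna()
    Y = wide.to_numpy(float)
    n, k = Y.shape
    if n < 2 or k < 2:
        raise ValueError("underpowered design: need >= 2 complete subjects and 2 levels")
    grand = Y.mean()
    ss_total = float(((Y - grand) ** 2).sum())
    ss_subj = float(k * ((Y.mean(axis=1) - grand) ** 2).sum())
    ss_within_factor = float(n * ((Y.mean(axis=0) - grand) ** 2).sum())

    level_means = {lv: float(m) for lv, m in zip(wide.columns, Y.mean(axis=0))}
    level_ns = {lv: n for lv in wide.columns}
    rows = []

    if between is None:
        ss_err = ss_total - ss_subj - ss_within_factor
        df_w, df_err = k - 1, (n - 1) * (k - 1)
        ms_w, ms_err = ss_within_factor / df_w, ss_err / df_err
        eps = _gg_epsilon(Y) if gg_correction else 1.0
        # degenerate residual (exact additivity): no evidence against H0 when
        # the effect SS is zero too
        F = ms_w / ms_err if ms_err > 0 else (0.0 if ms_w <= 1e-12 else np.inf)
        p = float(sst.f.sf(F, eps * df_w, eps * df_err))
        rows.append({"effect": within, "ss": ss_within_factor, "df": df_w, "ms": ms_w, "F": F, "p": p})
        rows.append({"effect": "subject", "ss": ss_subj, "df": n - 1, "ms": ss_subj / (n - 1),
                     "F": np.nan, "p": np.nan})
        rows.append({"effect": "error", "ss": ss_err, "df": df_err, "ms": ms_err,
                     "F": np.nan, "p": np.nan})
        if gg_correction:
            for r in rows:
                r["gg_eps"] = eps
    else:
        groups = data.drop_duplicates(subject).set_index(subject)[between]
        g = groups.loc[wide.index].to_numpy()
        labels = pd.unique(g)
        n_g = {lab: int((g == lab).sum()) for lab in labels}
        if min(n_g.values()) < 2:
            raise ValueError("underpowered design: need >= 2 subjects per group")
        # between-subjects stratum
        ss_between = float(sum(k * n_g[lab] * (Y[g == lab].mean() - grand) ** 2 for lab in labels))
        ss_subj_within = ss_subj - ss_between
        df_b, df_sw = len(labels) - 1, n - len(labels)
        # within-subjects stratum
        ss_inter = 0.0
        for lab in labels:
            Yg = Y[g == lab]
            ss_inter += float(
                n_g[lab]
                * ((Yg.mean(axis=0) - Yg.mean() - Y.mean(axis=0) + grand) ** 2).sum()
            )
        ss_err = ss_total - ss_between - ss_subj_within - ss_within_factor - ss_inter
        df_w = k - 1
        df_err = (n - len(labels)) * (k - 1)
        ms_err = ss_err / df_err
        rows.append({"effect": between, "ss": ss_between, "df": df_b,
                     "ms": ss_between / df_b,
                     "F": (ss_between / df_b) / (ss_subj_within / df_sw),
                     "p": float(sst.f.sf((ss_between / df_b) / (ss_subj_within / df_sw), df_b, df_sw))})
        rows.append({"effect": f"subject({between})", "ss": ss_subj_within, "df": df_sw,
                     "ms": ss_subj_within / df_sw, "F": np.nan, "p": np.nan})
        for name, ss, df1 in ((within, ss_within_factor, df_w),
                              (f"{within}:{between}", ss_inter, df_b * df_w)):
            F = (ss / df1) / ms_err
            rows.append({"effect": name, "ss": ss, "df": df1, "ms": ss / df1,
                         "F": F, "p": float(sst.f.sf(F, df1, df_err))})
        rows.append({"effect": "error", "ss": ss_err, "df": df_err, "ms": ms_err,
                     "F": np.nan, "p": np.nan})

    table = pd.DataFrame(rows)
    return AnovaResult(
        table=table,
        ms_error=float(ss_err / df_err),
        df_error=float(df_err),
        level_means=level_means,
        level_ns=level_ns,
        n_subjects=n,
    )


# ---------------------------------------------------------------------------
# Tukey HSD + compact letter display


def compact_letter_display(levels, nonsig_pairs) -> dict:
    """Compact letter display from the non-significant pair graph.

    ``levels`` are ordered (typically by descending mean).  Each letter
    labels a maximal set of mutually non-different levels, so two levels
    share a letter iff their difference is not significant and the display
    is exactly consistent with the post-hoc table.
    """
    levels = list(levels)
    nonsig = set(frozenset(p) for p in nonsig_pairs)

    def is_clique(members) -> bool:
        return all(frozenset(p) in nonsig for p in itertools.combinations(members, 2))

    # maximal cliques by subset enumeration; level counts here are small
    cliques: list[tuple] = []
    for r in range(len(levels), 0, -1):
        for combo in itertools.combinations(levels, r):
            if is_clique(combo) and not any(set(combo) <= set(c) for c in cliques):
                cliques.append(combo)
    cliques.sort(key=lambda c: min(levels.index(lv) for lv in c))
    letters = {lv: "" for lv in levels}
    for letter, grp in zip(string.ascii_lowercase, cliques):
        for lv in levels:
            if lv in grp:
                letters[lv] += letter
    return letters


def tukey_hsd(
    level_means: dict,
    level_ns: dict,
    ms_error: float,
    df_error: float,
    alpha: float = ALPHA,
) -> tuple[pd.DataFrame, dict]:
    """Studentized-range pairwise comparisons (Tukey-Kramer for unequal n).

    Returns the pairwise table and a compact letter display at ``alpha``.
    """
    if ms_error <= 0:
        raise ValueError("invalid error term: ms_error must be positive")
    levels = sorted(level_means, key=lambda lv: -level_means[lv])
    k = len(levels)
    rows = []
    nonsig = []
    for a, b in itertools.combinations(levels, 2):
        se = math.sqrt(ms_error / 2.0 * (1.0 / level_ns[a] + 1.0 / level_ns[b]))
        q = abs(level_means[a] - level_means[b]) / se if se > 0 else np.inf
        p_adj = float(sst.studentized_range.sf(q, k, df_error)) if k > 1 else 1.0
        p_adj = min(1.0, p_adj)
        rows.append({"level_i": a, "level_j": b,
                     "diff": level_means[a] - level_means[b], "q": q, "p_adj": p_adj})
        if p_adj > alpha:
            nonsig.append((a, b))
    letters = compact_letter_display(levels, nonsig)
    return pd.DataFrame(rows), letters


def anova_with_posthoc(data: pd.DataFrame, alpha: float = ALPHA, **kwargs) -> AnovaResult:
    """RM-ANOVA followed by Tukey HSD on the within-factor level means."""
    res = rm_anova(data, **kwargs)
    res.posthoc, res.letters = tukey_hsd(
        res.level_means, res.level_ns, res.ms_error, res.df_error, alpha
    )
    return res


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum


def wilcoxon_rank_sum(a, b) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test; returns (rank sum of ``a``, p).

    Exact p by full enumeration of rank assignments (midranks under ties)
    when min(n_a, n_b) <= 8 and n_a + n_b <= 16; otherwise the normal
    approximation with tie correction and continuity correction.  The exact
    two-sided p doubles the smaller tail (capped at 1).
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    na, nb = a.size, b.size
    n = na + nb
    ranks = sst.rankdata(np.concatenate([a, b]))
    w = float(ranks[:na].sum())
    if min(na, nb) <= 8 and n <= 16:
        return w, _exact_enumeration_p(ranks, na, w)
    return w, _normal_approx_p(ranks, na, w)


def _exact_enumeration_p(ranks: np.ndarray, na: int, w: float | None = None) -> float:
    """Two-sided exact p over all C(n, na) rank assignments (midranks kept)."""
    n = ranks.size
    if w is None:
        w = float(ranks[:na].sum())
    total = count_le = count_ge = 0
    for comb in itertools.combinations(range(n), na):
        ws = ranks[list(comb)].sum()
        total += 1
        if ws <= w + 1e-9:
            count_le += 1
        if ws >= w - 1e-9:
            count_ge += 1
    return min(1.0, 2.0 * min(count_le, count_ge) / total)


def _normal_approx_p(ranks: np.ndarray, na: int, w: float | None = None) -> float:
    """Normal approximation with tie and continuity corrections."""
    n = ranks.size
    nb = n - na
    if w is None:
        w = float(ranks[:na].sum())
    mu = na * (n + 1) / 2.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (n * (n - 1))
    var = na * nb / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return 1.0
    d = w - mu
    z = (d - 0.5 * np.sign(d)) / math.sqrt(var)
    return float(min(1.0, 2.0 * sst.norm.sf(abs(z))))


# ---------------------------------------------------------------------------
# dose-response tables, ratios, ranking


def build_dose_response(
    cohort: pd.DataFrame,
    value_col: str = "bouts",
    group_cols: tuple[str, str, str] = ("strain", "pruritogen", "dose_fold"),
) -> pd.DataFrame:
    """Cell means, SEMs and n per strain x pruritogen x dose.

    Expects outlier removal to have been applied already (see
    :func:`apply_outlier_fences`).  ``sem`` is NaN and flagged undefined for
    n = 1 cells; the peak dose per curve is the argmax of cell means with
    ties resolved toward the lower dose.
    """
    if cohort.empty:
        raise ValueError("missing group: empty cohort")
    rows = []
    for (strain, prur, dose), g in cohort.groupby(list(group_cols), sort=True):
        x = g[value_col].to_numpy(float)
        if x.size == 0:
            raise ValueError(f"missing group: {strain}/{prur}/{dose}")
        n = x.size
        sem = float(np.std(x, ddof=1) / np.sqrt(n)) if n > 1 else np.nan
        rows.append({
            "strain": strain, "pruritogen": prur, "dose_fold": float(dose),
            "n": n, "mean": float(x.mean()), "sem": sem, "sem_defined": n > 1,
        })
    table = pd.DataFrame(rows)
    table["is_peak"] = False
    for _, g in table.groupby(["strain", "pruritogen"]):
        g_sorted = g.sort_values("dose_fold")  # ties -> lower dose wins via idxmax on sorted
        peak_idx = g_sorted["mean"].idxmax()
        table.loc[peak_idx, "is_peak"] = True
    return table


def dose_response_from_anchors(mean_table: dict, strain: str) -> pd.DataFrame:
    """A dose-response table taken directly from an anchor mean table.

    Used when the per-animal data behind a published summary is not
    available: the cells carry the stated mean/SEM/n.
    """
    rows = []
    for prur, cell in mean_table[strain].items():
        for dose, dspec in cell["doses"].items():
            rows.append({
                "strain": strain, "pruritogen": prur, "dose_fold": float(dose),
                "n": cell["n"], "mean": float(dspec["mean"]), "sem": float(dspec["sem"]),
                "sem_defined": True, "source": dspec.get("source", "unspecified"),
            })
    table = pd.DataFrame(rows).sort_values(["pruritogen", "dose_fold"]).reset_index(drop=True)
    table["is_peak"] = False
    for _, g in table.groupby("pruritogen"):
        table.loc[g.sort_values("dose_fold")["mean"].idxmax(), "is_peak"] = True
    return table


def peak_ratio_report(c57_table: pd.DataFrame, c3h_table: pd.DataFrame) -> pd.DataFrame:
    """Cross-strain peak comparison per pruritogen.

    ``percent`` = 100 x (C3H peak mean) / (C57 peak mean), rounded to the
    nearest integer; ``fold`` = (C57 peak) / (C3H peak) to one decimal.  Raw
    values are reported alongside; raw percent x raw fold = 100 exactly.
    """
    report = []
    prurs = sorted(set(c57_table["pruritogen"]) & set(c3h_table["pruritogen"]))
    if not prurs:
        raise ValueError("tables share no pruritogen")
    for prur in prurs:
        peak_c57 = c57_table.loc[c57_table["pruritogen"] == prur, "mean"].max()
        peak_c3h = c3h_table.loc[c3h_table["pruritogen"] == prur, "mean"].max()
        if peak_c57 <= 0:
            raise ValueError(f"undefined ratio: zero C57 peak for {prur}")
        percent_raw = 100.0 * peak_c3h / peak_c57
        fold_raw = peak_c57 / peak_c3h if peak_c3h > 0 else np.inf
        report.append({
            "pruritogen": prur,
            "peak_c57": float(peak_c57), "peak_c3h": float(peak_c3h),
            "percent_raw": percent_raw, "percent": int(round(percent_raw)),
            "fold_raw": fold_raw, "fold": round(fold_raw, 1),
        })
    return pd.DataFrame(report)


def rank_pruritogens(
    cohort: pd.DataFrame,
    value_col: str = "bouts",
    subject: str = "animal_id",
    alpha: float = ALPHA,
) -> pd.DataFrame:
    """Potency ranking of pruritogens within one strain.

    Each animal is reduced to its grand mean across doses; pruritogens are
    ranked by group mean of those values (descending) and compared by a
    one-way ANOVA with Tukey HSD, yielding homogeneous-mean letter groups.
    """
    if cohort["pruritogen"].nunique() < 2:
        raise ValueError("need >= 2 pruritogens")
    per_animal = (
        cohort.groupby([subject, "pruritogen"], sort=False)[value_col].mean().reset_index()
    )
    groups = {p: g[value_col].to_numpy(float) for p, g in per_animal.groupby("pruritogen")}
    means = {p: float(v.mean()) for p, v in groups.items()}
    ns = {p: int(v.size) for p, v in groups.items()}
    n_tot = sum(ns.values())
    k = len(groups)
    grand = per_animal[value_col].mean()
    ss_within = sum(float(((v - v.mean()) ** 2).sum()) for v in groups.values())
    df_err = n_tot - k
    ms_error = ss_within / df_err
    ss_between = sum(ns[p] * (means[p] - grand) ** 2 for p in groups)
    F = (ss_between / (k - 1)) / ms_error if ms_error > 0 else np.inf
    posthoc, letters = tukey_hsd(means, ns, ms_error, df_err, alpha)
    order = sorted(means, key=lambda p: -means[p])
    out = pd.DataFrame({
        "pruritogen": order,
        "grand_mean": [means[p] for p in order],
        "n": [ns[p] for p in order],
        "rank": np.arange(1, len(order) + 1),
        "letters": [letters[p] for p in order],
    })
    out.attrs["anova"] = {"F": float(F), "df": (k - 1, df_err),
                          "p": float(sst.f.sf(F, k - 1, df_err))}
    out.attrs["posthoc"] = posthoc
    return out
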