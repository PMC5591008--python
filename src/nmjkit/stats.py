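"""Group comparison via a deterministic statistical decision tree.

The router reproduces a conventional SPSS-style workflow for comparing
per-genotype NMJ and locomotion measurements at a 95% confidence level:

1. *Normality* is assessed per group from sample skewness and excess
   kurtosis: the data are treated as non-normal if, for any group,
   either moment exceeds 1.96 times its finite-sample standard error.
2. *Variance homogeneity* across groups is assessed with Levene's test
   (centered on the mean); variances are unequal if p < 0.05.
3. Routing:

   ========== ============== ===== ===========================================
   normal     homogeneous    k     test (post hoc)
   ========== ============== ===== ===========================================
   yes        yes            2     Student t
   yes        yes            >2    one-way ANOVA (Dunnett vs control, else
                                   Bonferroni all pairs)
   yes        no             any   Welch ANOVA (Games-Howell)
   no         --             2     Mann-Whitney U
   no         --             >2    Kruskal-Wallis (Dunn, Bonferroni-adjusted)
   ========== ============== ===== ===========================================

Categorical data are compared with Pearson's chi-squared test and
Bonferroni-corrected pairwise comparisons.  The module also houses the
pull-down proteomics candidate filter (>= 2 high-confidence peptides,
absent from mock controls).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "NormalityAssessment",
    "GroupComparisonResult",
    "se_skewness",
    "se_kurtosis",
    "assess_normality",
    "assess_variance_homogeneity",
    "select_and_run",
    "dunn_test",
    "categorical_test",
    "CategoricalResult",
    "filter_pulldown_candidates",
]


def _split_groups(table: pd.DataFrame, min_n: int = 2) -> dict[str, np.ndarray]:
    if not {"group", "value"} <= set(table.columns):
        raise ValueError("table needs 'group' and 'value' columns")
    values = table["value"].to_numpy(dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("values must be finite")
    out: dict[str, np.ndarray] = {}
    for label, sub in table.groupby("group", sort=False):
        v = sub["value"].to_numpy(dtype=float)
        if len(v) < min_n:
            raise ValueError(f"group {label!r} has n={len(v)} < {min_n}")
        out[str(label)] = v
    if len(out) < 2:
        raise ValueError("need at least 2 groups")
    return out


def se_skewness(n: int) -> float:
    """Finite-sample standard error of sample skewness (G1)."""
    if n < 3:
        raise ValueError("skewness SE needs n >= 3")
    return float(np.sqrt(6.0 * n * (n - 1) / ((n - 2) * (n + 1) * (n + 3))))


def se_kurtosis(n: int) -> float:
    """Finite-sample standard error of sample excess kurtosis (G2)."""
    if n < 4:
        raise ValueError("kurtosis SE needs n >= 4")
    return float(
        2.0 * se_skewness(n) * np.sqrt((n**2 - 1.0) / ((n - 3.0) * (n + 5.0)))
    )


@dataclass(frozen=True)
class NormalityAssessment:
    """Per-group moment-based normality screen.

    ``normal`` is True only if *every* group satisfies
    ``|skewness| <= 1.96 * SE_skew`` and ``|kurtosis| <= 1.96 * SE_kurt``
    (bias-corrected sample moments, excess kurtosis).
    """

    per_group: pd.DataFrame
    normal: bool


def assess_normality(table: pd.DataFrame, z_crit: float = 1.96) -> NormalityAssessment:
    """Moment-based normality screen of every group in a table."""
    groups = _split_groups(table, min_n=4)
    rows = []
    for label, v in groups.items():
        n = len(v)
        g1 = float(sps.skew(v, bias=False))
        g2 = float(sps.kurtosis(v, fisher=True, bias=False))
        ses, sek = se_skewness(n), se_kurtosis(n)
        ok = abs(g1) <= z_crit * ses and abs(g2) <= z_crit * sek
        rows.append(
            {
                "group": label, "n": n,
                "skewness": g1, "se_skewness": ses,
                "kurtosis": g2, "se_kurtosis": sek,
                "normal": ok,
            }
        )
    per_group = pd.DataFrame(rows)
    return NormalityAssessment(per_group=per_group, normal=bool(per_group["normal"].all()))


def assess_variance_homogeneity(
    table: pd.DataFrame, alpha: float = 0.05
) -> tuple[bool, float, float]:
    """Levene's test (mean-centered); homogeneous iff p >= alpha.

    Returns ``(homogeneous, statistic, p)``.  If every group is constant
    the test is undefined; the data are flagged homogeneous with a
    warning.
    """
    groups = _split_groups(table, min_n=2)
    if all(np.ptp(v) == 0 for v in groups.values()):
        warnings.warn("all groups constant: Levene undefined, assuming homogeneity",
                      stacklevel=2)
        return True, float("nan"), float("nan")
    stat, p = sps.levene(*groups.values(), center="mean")
    return bool(p >= alpha), float(stat), float(p)


@dataclass(frozen=True)
class GroupComparisonResult:
    """Outcome of the decision tree on one measurement table."""

    routing: dict
    test_name: str
    statistic: float
    p_value: float
    alpha: float
    posthoc_method: str | None
    posthoc: pd.DataFrame | None

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


def dunn_test(groups: dict[str, np.ndarray], adjust: str = "bonferroni") -> pd.DataFrame:
    """Dunn's rank-based pairwise comparisons after Kruskal-Wallis.

    All observations are ranked jointly (average ranks on ties); for
    each pair the statistic is the difference in mean ranks divided by
    its standard error under H0 with tie correction:

    ``z = (R_i - R_j) / sqrt((N(N+1)/12 - T/(12(N-1))) (1/n_i + 1/n_j))``

    where ``T = sum(t^3 - t)`` over groups of tied values.  Two-sided
    normal p-values are Bonferroni-adjusted over all pairs.
    """
    labels = list(groups)
    values = np.concatenate([groups[g] for g in labels])
    sizes = np.array([len(groups[g]) for g in labels])
    n_total = len(values)
    ranks = sps.rankdata(values)
    bounds = np.concatenate([[0], np.cumsum(sizes)])
    mean_ranks = {
        g: ranks[a:b].mean() for g, a, b in zip(labels, bounds[:-1], bounds[1:])
    }
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term / (12.0 * (n_total - 1))

    rows = []
    m = len(labels) * (len(labels) - 1) // 2
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            gi, gj = labels[i], labels[j]
            se = np.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
            z = (mean_ranks[gi] - mean_ranks[gj]) / se
            p_raw = float(2.0 * sps.norm.sf(abs(z)))
            if adjust == "bonferroni":
                p_adj = min(1.0, m * p_raw)
            elif adjust == "none":
                p_adj = p_raw
            else:
                raise ValueError(f"unknown adjustment {adjust!r}")
            rows.append(
                {"group1": gi, "group2": gj, "z": float(z),
                 "p_raw": p_raw, "p_adj": p_adj}
            )
    return pd.DataFrame(rows)


def _bonferroni_pairwise_t(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    """All-pairs t comparisons on the pooled within-group variance (ANOVA MSE)."""
    labels = list(groups)
    n_total = sum(len(v) for v in groups.values())
    k = len(labels)
    mse = sum(
        np.sum((v - v.mean()) ** 2) for v in groups.values()
    ) / (n_total - k)
    df = n_total - k
    m = k * (k - 1) // 2
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            vi, vj = groups[labels[i]], groups[labels[j]]
            se = np.sqrt(mse * (1.0 / len(vi) + 1.0 / len(vj)))
            t = (vi.mean() - vj.mean()) / se
            p_raw = float(2.0 * sps.t.sf(abs(t), df))
            rows.append(
                {"group1": labels[i], "group2": labels[j], "t": float(t),
                 "p_raw": p_raw, "p_adj": min(1.0, m * p_raw)}
            )
    return pd.DataFrame(rows)


def _games_howell(table: pd.DataFrame) -> pd.DataFrame:
    import pingouin as pg

    gh = pg.pairwise_gameshowell(data=table, dv="value", between="group")
    return pd.DataFrame(
        {"group1": gh["A"].astype(str), "group2": gh["B"].astype(str),
         "t": gh["T"].astype(float), "p_adj": gh["pval"].astype(float)}
    )


def _welch_anova(table: pd.DataFrame) -> tuple[float, float]:
    import pingouin as pg

    res = pg.welch_anova(data=table, dv="value", between="group")
    return float(res["F"].iloc[0]), float(res["p_unc"].iloc[0])


def select_and_run(
    table: pd.DataFrame,
    control_label: str | None = None,
    alpha: float = 0.05,
) -> GroupComparisonResult:
    """Route a measurement table through the decision tree and run the test.

    ``control_label``, when given, selects Dunnett's comparisons to a
    control for the normal/homogeneous many-group branch; otherwise all
    pairs are compared with Bonferroni correction.  Post-hoc comparisons
    are only run for more than two groups.
    """
    groups = _split_groups(table, min_n=4)
    labels = list(groups)
    k = len(labels)
    if control_label is not None and control_label not in labels:
        raise ValueError(f"control {control_label!r} not among groups {labels}")

    normality = assess_normality(table)
    homogeneous, lev_stat, lev_p = assess_variance_homogeneity(table, alpha=alpha)
    routing = {
        "k": k,
        "normal": normality.normal,
        "homogeneous": homogeneous,
        "levene_p": lev_p,
        "control": control_label,
    }

    posthoc = None
    posthoc_method = None
    if normality.normal and homogeneous:
        if k == 2:
            test_name = "student_t"
            stat, p = sps.ttest_ind(groups[labels[0]], groups[labels[1]], equal_var=True)
        else:
            test_name = "one_way_anova"
            stat, p = sps.f_oneway(*groups.values())
            if control_label is not None:
                others = [g for g in labels if g != control_label]
                res = sps.dunnett(
                    *[groups[g] for g in others], control=groups[control_label]
                )
                posthoc_method = "dunnett"
                posthoc = pd.DataFrame(
                    {"group1": others, "group2": control_label,
                     "t": res.statistic, "p_adj": res.pvalue}
                )
            else:
                posthoc_method = "bonferroni"
                posthoc = _bonferroni_pairwise_t(groups)
    elif normality.normal:
        test_name = "welch_anova"
        stat, p = _welch_anova(table)
        if k > 2:
            posthoc_method = "games_howell"
            posthoc = _games_howell(table)
    else:
        if k == 2:
            test_name = "mann_whitney_u"
            stat, p = sps.mannwhitneyu(
                groups[labels[0]], groups[labels[1]], alternative="two-sided"
            )
        else:
            test_name = "kruskal_wallis"
            stat, p = sps.kruskal(*groups.values())
            posthoc_method = "dunn"
            posthoc = dunn_test(groups)

    return GroupComparisonResult(
        routing=routing,
        test_name=test_name,
        statistic=float(stat),
        p_value=float(p),
        alpha=alpha,
        posthoc_method=posthoc_method,
        posthoc=posthoc,
    )


@dataclass(frozen=True)
class CategoricalResult:
    chi2: float
    p_value: float
    dof: int
    pairwise: pd.DataFrame | None


def categorical_test(counts: pd.DataFrame | np.ndarray) -> CategoricalResult:
    """Pearson chi-squared test of a category x group contingency table.

    Columns are groups.  For more than two groups, every pair of group
    columns is compared with its own chi-squared test and the p-values
    are Bonferroni-adjusted over the number of pairs.  No continuity
    correction is applied (plain Pearson statistic).
    """
    if isinstance(counts, pd.DataFrame):
        table = counts.to_numpy()
        group_names = [str(c) for c in counts.columns]
    else:
        table = np.asarray(counts)
        group_names = [f"g{i}" for i in range(table.shape[1])]
    if table.ndim != 2 or table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("contingency table must be at least 2x2")
    if np.any(table < 0) or not np.issubdtype(np.asarray(table).dtype, np.number):
        raise ValueError("counts must be non-negative numbers")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("contingency table has a zero margin")

    chi2, p, dof, _ = sps.chi2_contingency(table, correction=False)
    pairwise = None
    k = table.shape[1]
    if k > 2:
        m = k * (k - 1) // 2
        rows = []
        for i in range(k):
            for j in range(i + 1, k):
                sub = table[:, [i, j]]
                sub = sub[sub.sum(axis=1) > 0]
                c2, pr, _, _ = sps.chi2_contingency(sub, correction=False)
                rows.append(
                    {"group1": group_names[i], "group2": group_names[j],
                     "chi2": float(c2), "p_raw": float(pr),
                     "p_adj": min(1.0, m * float(pr))}
                )
        pairwise = pd.DataFrame(rows)
    return CategoricalResult(chi2=float(chi2), p_value=float(p), dof=int(dof),
                             pairwise=pairwise)


def filter_pulldown_candidates(
    sample: pd.DataFrame,
    control: pd.DataFrame,
    min_peptides: int = 2,
) -> list[str]:
    """Candidate interactors from pull-down mass-spectrometry tables.

    A protein is a candidate iff it is present in the bait sample with
    at least ``min_peptides`` high-confidence peptides and absent from
    the mock-transfected control.  Tables need columns ``protein`` and
    ``peptides`` (control may list proteins with any peptide count:
    presence alone excludes).  The returned list preserves the sample
    table's order.
    """
    for name, df in (("sample", sample), ("control", control)):
        if "protein" not in df.columns:
            raise ValueError(f"{name} table needs a 'protein' column")
    if "peptides" not in sample.columns:
        raise ValueError("sample table needs a 'peptides' column")
    if (sample["peptides"] < 0).any():
        raise ValueError("peptide counts must be >= 0")
    in_control = set(control["protein"].astype(str))
    keep = sample[
        (sample["peptides"] >= min_peptides)
        & ~sample["protein"].astype(str).isin(in_control)
    ]
    return [str(p) for p in keep["protein"]]
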