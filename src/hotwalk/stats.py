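"""Three-group comparison statistics with assumption-driven branching.

The decision tree mirrors common clinical-neuropsychology reporting: for each
continuous feature, Kolmogorov-Smirnov (Lilliefors) normality per group and
Levene's variance-homogeneity test decide the omnibus method — one-way ANOVA
with Bonferroni-adjusted pairwise pooled t tests when both assumptions hold,
otherwise Kruskal-Wallis with Dunn's rank-based pairwise tests (tie-corrected,
Bonferroni-adjusted).  Adjusted p values are capped at 0.999, the table
convention of the source software.  Across the trajectory-mining feature
family the pairwise comparisons are additionally corrected by
Benjamini-Hochberg FDR.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.diagnostic import lilliefors
from statsmodels.stats.multitest import multipletests

from .errors import DegenerateDataError, ValidationError
from .trajectory import GROUPS, MINING_FEATURES

P_CAP = 0.999
PAIRS = (("AD", "aMCI"), ("AD", "NC"), ("aMCI", "NC"))


def _cap(p: float) -> float:
    return min(float(p), P_CAP)


@dataclass(frozen=True)
class PairwiseResult:
    pair: tuple[str, str]
    method: str
    statistic: float
    p_raw: float
    p_adjusted: float


@dataclass
class TestResult:
    """Omnibus + post hoc outcome for one feature."""

    feature: str
    omnibus_method: str  # "one-way ANOVA" or "Kruskal-Wallis"
    statistic: float
    p_value: float
    normality: dict[str, bool] = field(default_factory=dict)
    variance_homogeneous: bool = False
    pairwise: dict[tuple[str, str], PairwiseResult] = field(default_factory=dict)


@dataclass(frozen=True)
class CorrelationResult:
    var_x: str
    var_y: str
    r: float
    p: float
    n: int


# ---------------------------------------------------------------------------
# Assumption checks
# ---------------------------------------------------------------------------


def normality_test(sample, alpha: float = 0.05, n_sim: int = 2000):
    """Lilliefors-type KS test of normality with estimated mean/SD.

    Returns ``(statistic, p, passed)`` where ``passed`` is ``p >= alpha``.
    Uses the statsmodels table approximation; for n < 4 (below the table's
    range) the null distribution of the statistic is simulated
    parametrically with ``n_sim`` replicates.
    """
    x = np.asarray(sample, dtype=float)
    if x.size < 3:
        raise DegenerateDataError("normality test needs at least 3 observations")
    if np.ptp(x) == 0:
        raise DegenerateDataError("normality test undefined for a constant sample")
    if x.size >= 4:
        stat, p = lilliefors(x, dist="norm", pvalmethod="table")
    else:
        stat = sps.kstest(x, "norm", args=(x.mean(), x.std(ddof=1))).statistic
        rng = np.random.default_rng(12345)
        null = np.empty(n_sim)
        for i in range(n_sim):
            z = rng.standard_normal(x.size)
            null[i] = sps.kstest(z, "norm", args=(z.mean(), z.std(ddof=1))).statistic
        p = float(np.mean(null >= stat))
    return float(stat), float(p), bool(p >= alpha)


def variance_test(groups, alpha: float = 0.05):
    """Levene's test (center = mean) of equal variances across groups."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2 or any(a.size < 2 for a in arrays):
        raise DegenerateDataError("Levene's test needs >= 2 groups with >= 2 values")
    if all(np.ptp(a) == 0 for a in arrays):
        raise DegenerateDataError("Levene's test undefined when every group is constant")
    with np.errstate(invalid="ignore"):
        stat, p = sps.levene(*arrays, center="mean")
    if not (np.isfinite(stat) and np.isfinite(p)):
        # zero spread of absolute deviations in every group: no evidence
        # against homogeneity
        return 0.0, 1.0, True
    return float(stat), float(p), bool(p >= alpha)


# ---------------------------------------------------------------------------
# Post hoc batteries
# ---------------------------------------------------------------------------


def dunn_pairwise(groups: dict[str, np.ndarray], n_comparisons: int | None = None):
    """Dunn's rank-based pairwise z tests with tie correction.

    ``groups`` maps label -> values.  Returns {(a, b): PairwiseResult} with
    two-sided p values Bonferroni-adjusted over the number of comparisons
    (default: all pairs) and capped at 0.999.
    """
    labels = list(groups)
    if len(labels) < 2:
        raise DegenerateDataError("Dunn's test needs at least 2 groups")
    pooled = np.concatenate([np.asarray(groups[g], dtype=float) for g in labels])
    sizes = {g: len(groups[g]) for g in labels}
    n = pooled.size
    ranks = sps.rankdata(pooled)
    mean_ranks = {}
    start = 0
    for g in labels:
        mean_ranks[g] = ranks[start:start + sizes[g]].mean()
        start += sizes[g]
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts ** 3 - counts))
    base_var = n * (n + 1) / 12.0 - tie_term / (12.0 * (n - 1))

    pairs = list(itertools.combinations(labels, 2))
    m = n_comparisons if n_comparisons is not None else len(pairs)
    out = {}
    for a, b in pairs:
        var = base_var * (1.0 / sizes[a] + 1.0 / sizes[b])
        if var <= 0:
            z, p = 0.0, 1.0
        else:
            z = (mean_ranks[a] - mean_ranks[b]) / math.sqrt(var)
            p = 2.0 * sps.norm.sf(abs(z))
        out[(a, b)] = PairwiseResult((a, b), "Dunn", float(z), float(p),
                                     _cap(p * m))
    return out


def bonferroni_t_pairwise(groups: dict[str, np.ndarray],
                          n_comparisons: int | None = None):
    """Pairwise two-sample pooled-variance t tests, Bonferroni-adjusted."""
    pairs = list(itertools.combinations(list(groups), 2))
    m = n_comparisons if n_comparisons is not None else len(pairs)
    out = {}
    for a, b in pairs:
        xa, xb = np.asarray(groups[a], float), np.asarray(groups[b], float)
        if np.ptp(np.concatenate([xa, xb])) == 0:
            t, p = 0.0, 1.0
        else:
            t, p = sps.ttest_ind(xa, xb, equal_var=True)
        out[(a, b)] = PairwiseResult((a, b), "Bonferroni t", float(t), float(p),
                                     _cap(float(p) * m))
    return out


def mannwhitney_pairwise(groups: dict[str, np.ndarray],
                         n_comparisons: int | None = None):
    """Pairwise Mann-Whitney U tests, Bonferroni-adjusted."""
    pairs = list(itertools.combinations(list(groups), 2))
    m = n_comparisons if n_comparisons is not None else len(pairs)
    out = {}
    for a, b in pairs:
        xa, xb = np.asarray(groups[a], float), np.asarray(groups[b], float)
        if np.ptp(np.concatenate([xa, xb])) == 0:
            u, p = len(xa) * len(xb) / 2.0, 1.0
        else:
            u, p = sps.mannwhitneyu(xa, xb, alternative="two-sided")
        out[(a, b)] = PairwiseResult((a, b), "Mann-Whitney U", float(u),
                                     float(p), _cap(float(p) * m))
    return out


# ---------------------------------------------------------------------------
# Omnibus comparison
# ---------------------------------------------------------------------------


def omnibus_compare(
    groups: dict[str, np.ndarray],
    feature: str = "",
    alpha: float = 0.05,
    posthoc: str = "auto",
) -> TestResult:
    """Assumption-checked three-group comparison of one feature.

    If every group passes Lilliefors normality and Levene's test passes,
    runs one-way ANOVA with Bonferroni pairwise t tests; otherwise
    Kruskal-Wallis with Dunn's pairwise tests.  A constant group is treated
    as failing normality.  ``posthoc`` may force "bonferroni", "dunn" or
    "mannwhitney" regardless of the branch.
    """
    if posthoc not in ("auto", "bonferroni", "dunn", "mannwhitney"):
        raise ValidationError(f"unknown posthoc option {posthoc!r}")
    arrays = {g: np.asarray(v, dtype=float) for g, v in groups.items()}
    if len(arrays) < 2 or any(a.size < 2 for a in arrays.values()):
        raise DegenerateDataError("need >= 2 groups with >= 2 observations each")

    # groups too small for the normality test, or constant, fail the
    # normality assumption and push the branch to Kruskal-Wallis
    normality = {}
    for g, a in arrays.items():
        if a.size < 3 or np.ptp(a) == 0:
            normality[g] = False
        else:
            normality[g] = normality_test(a, alpha=alpha)[2]
    try:
        var_ok = variance_test(arrays.values(), alpha=alpha)[2]
    except DegenerateDataError:
        var_ok = False

    pooled = np.concatenate(list(arrays.values()))
    degenerate = np.ptp(pooled) == 0

    parametric = all(normality.values()) and var_ok
    if degenerate:
        method, stat, p = ("Kruskal-Wallis", 0.0, 1.0)
    elif parametric:
        stat, p = sps.f_oneway(*arrays.values())
        method = "one-way ANOVA"
    else:
        stat, p = sps.kruskal(*arrays.values())
        method = "Kruskal-Wallis"

    if posthoc == "auto":
        posthoc = "bonferroni" if parametric else "dunn"
    battery = {"bonferroni": bonferroni_t_pairwise,
               "dunn": dunn_pairwise,
               "mannwhitney": mannwhitney_pairwise}[posthoc]
    pairwise = battery(arrays)

    return TestResult(
        feature=feature,
        omnibus_method=method,
        statistic=float(stat),
        p_value=float(p),
        normality=normality,
        variance_homogeneous=bool(var_ok),
        pairwise=pairwise,
    )


# ---------------------------------------------------------------------------
# Categorical, correlation, FDR
# ---------------------------------------------------------------------------


def chi_square_categorical(table):
    """Pearson chi-square (no continuity correction) on a contingency table.

    Rows are groups.  For three-row tables (e.g. sex ratio by group) the
    three 2 x 2 sub-tables are also tested, Bonferroni-adjusted over 3.
    Returns ``(statistic, p, pairwise)`` where pairwise maps row-index pairs
    to adjusted p values (empty unless the table has exactly 3 rows).
    """
    tab = np.asarray(table, dtype=float)
    if tab.ndim != 2 or tab.shape[0] < 2 or tab.shape[1] < 2:
        raise ValidationError("contingency table must be at least 2 x 2")
    if np.any(tab < 0):
        raise ValidationError("counts must be non-negative")
    if np.any(tab.sum(axis=0) == 0) or np.any(tab.sum(axis=1) == 0):
        raise DegenerateDataError("contingency table has a zero margin")
    stat, p, _, _ = sps.chi2_contingency(tab, correction=False)
    pairwise = {}
    if tab.shape[0] == 3:
        for i, j in itertools.combinations(range(3), 2):
            sub = tab[[i, j], :]
            if np.any(sub.sum(axis=0) == 0):
                pairwise[(i, j)] = P_CAP
                continue
            s, praw, _, _ = sps.chi2_contingency(sub, correction=False)
            pairwise[(i, j)] = _cap(praw * 3)
    return float(stat), float(p), pairwise


def pearson_correlations(
    scores: pd.DataFrame,
    covariates: pd.DataFrame,
    on: str = "participant_id",
) -> list[CorrelationResult]:
    """Pearson r between every score column and every covariate column.

    Both tables must carry the join key ``on``; each correlation uses the
    participants with both values present (pairwise deletion) and requires
    n >= 3 and non-constant variables.
    """
    merged = scores.merge(covariates, on=on, suffixes=("_score", "_cov"))
    score_cols = [c for c in scores.columns if c not in (on, "group")]
    cov_cols = [c for c in covariates.columns if c not in (on, "group")]
    out = []
    for sc in score_cols:
        xcol = sc if sc in merged.columns else f"{sc}_score"
        for cc in cov_cols:
            ycol = cc if cc in merged.columns else f"{cc}_cov"
            sub = merged[[xcol, ycol]].dropna()
            if len(sub) < 3:
                raise DegenerateDataError(
                    f"correlation of {sc!r} with {cc!r} has n < 3")
            x = sub[xcol].to_numpy(float)
            y = sub[ycol].to_numpy(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                raise DegenerateDataError(
                    f"correlation of {sc!r} with {cc!r} has a constant variable")
            r, p = sps.pearsonr(x, y)
            out.append(CorrelationResult(sc, cc, float(r), float(p), len(sub)))
    return out


def fdr_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValidationError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Feature-table report
# ---------------------------------------------------------------------------


def compare_all_features(
    table: pd.DataFrame,
    features: list[str] | None = None,
    fdr_family: list[str] | None = None,
    alpha: float = 0.05,
    posthoc: str = "auto",
):
    """Per-feature omnibus + post hoc over a participant-by-feature table.

    ``table`` needs a ``group`` column with the three study groups.  Within
    ``fdr_family`` (default: the trajectory-mining features present) the
    pairwise raw p values are jointly BH-FDR adjusted instead of the
    per-feature Bonferroni adjustment.  Returns ``(report, results)``: a
    tidy report frame (one row per feature: group means +- SD, omnibus
    method/p, pairwise adjusted p) and the full TestResult objects.
    """
    if "group" not in table.columns:
        raise ValidationError("feature table needs a 'group' column")
    if features is None:
        skip = {"participant_id", "group"}
        features = [c for c in table.columns if c not in skip]
    if fdr_family is None:
        fdr_family = [f for f in MINING_FEATURES if f in features]

    results: dict[str, TestResult] = {}
    for feat in features:
        groups = {g: table.loc[table["group"] == g, feat].to_numpy(float)
                  for g in GROUPS}
        results[feat] = omnibus_compare(groups, feature=feat, alpha=alpha,
                                        posthoc=posthoc)

    # joint BH-FDR over the mining family's pairwise comparisons
    family = [f for f in fdr_family if f in results]
    if family:
        raw = [results[f].pairwise[pair].p_raw for f in family for pair in PAIRS]
        adj = fdr_adjust(raw)
        k = 0
        for f in family:
            for pair in PAIRS:
                old = results[f].pairwise[pair]
                results[f].pairwise[pair] = PairwiseResult(
                    pair, old.method + " + FDR", old.statistic, old.p_raw,
                    _cap(adj[k]))
                k += 1

    rows = []
    for feat in features:
        res = results[feat]
        row = {"feature": feat}
        for g in GROUPS:
            vals = table.loc[table["group"] == g, feat].to_numpy(float)
            row[f"mean_{g}"] = vals.mean()
            row[f"sd_{g}"] = vals.std(ddof=1)
        row["omnibus_method"] = res.omnibus_method
        row["omnibus_p"] = res.p_value
        for a, b in PAIRS:
            row[f"p_{a}_vs_{b}"] = res.pairwise[(a, b)].p_adjusted
        rows.append(row)
    return pd.DataFrame(rows), results
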