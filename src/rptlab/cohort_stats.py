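"""Cohort-level summaries and nonparametric comparison of judgment features.

Per cohort and feature: mean, sample SD, SEM and a t-based 95% CI for the
mean, plus median/IQR for violin-style displays. Across cohorts: the
Kruskal–Wallis H-test (tie-corrected, chi-square reference with k-1 df),
Dunn's pairwise post-hoc z-tests on the pooled ranks with Holm step-down
correction, and pairwise two-sample Kolmogorov–Smirnov tests. Age effects
are probed with univariate OLS regressions of each feature on standardized
ordinal age, Bonferroni-corrected at 0.05/15.

Dunn's test is implemented here directly (pooled-rank z statistic with the
usual tie correction); the z formula is cross-checked in the test suite
against a brute-force rank computation.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .features import DIMENSIONLESS, FEATURE_NAMES

BONFERRONI_ALPHA = 0.05 / 15

#: default mapping of age bands to ordinal midpoints (years)
DEFAULT_AGE_MIDPOINTS: Mapping[str, float] = {
    "18-24": 21.0, "25-34": 29.5, "35-44": 39.5,
    "45-54": 49.5, "55-64": 59.5, "65+": 70.0,
}


@dataclass(frozen=True)
class FeatureSummary:
    cohort: str
    feature: str
    mean: float
    sd: float
    sem: float
    ci95_low: float
    ci95_high: float
    median: float
    iqr: float
    n: int


def feature_summary(values: Sequence[float] | np.ndarray, cohort: str = "",
                    feature: str = "") -> FeatureSummary:
    """Location/dispersion summary of one feature in one cohort.

    The 95% CI for the mean uses the t distribution with n-1 df.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    n = len(v)
    if n < 2:
        raise ValueError("need at least 2 finite values")
    mean = float(v.mean())
    sd = float(v.std(ddof=1))
    sem = sd / math.sqrt(n)
    tcrit = float(stats.t.ppf(0.975, n - 1))
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    return FeatureSummary(cohort, feature, mean, sd, sem,
                          mean - tcrit * sem, mean + tcrit * sem,
                          float(med), float(q3 - q1), n)


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Tie-corrected Kruskal–Wallis H and its chi-square p-value (k-1 df)."""
    if any(len(g) == 0 for g in groups):
        raise ValueError("empty group")
    h, p = stats.kruskal(*[np.asarray(g, float) for g in groups])
    return float(h), float(p)


def dunn_posthoc(
    groups: Sequence[Sequence[float]],
    labels: Sequence[str] | None = None,
    correction: str = "holm",
) -> pd.DataFrame:
    """Dunn's pairwise post-hoc test on pooled ranks, Holm-corrected.

    For groups i, j with mean pooled ranks r_i, r_j:
    ``z = (r_i - r_j) / sqrt((N(N+1)/12 - T) (1/n_i + 1/n_j))`` where
    ``T = sum(t^3 - t) / (12 (N - 1))`` over tie groups. Two-sided p-values
    are corrected across the pairs and returned as a symmetric matrix with
    unit diagonal.
    """
    k = len(groups)
    if labels is None:
        labels = [f"group{i}" for i in range(k)]
    arrays = [np.asarray(g, float) for g in groups]
    if any(len(a) == 0 for a in arrays):
        raise ValueError("empty group")
    pooled = np.concatenate(arrays)
    n_total = len(pooled)
    ranks = stats.rankdata(pooled)
    mean_ranks, sizes, start = [], [], 0
    for a in arrays:
        mean_ranks.append(ranks[start:start + len(a)].mean())
        sizes.append(len(a))
        start += len(a)
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n_total - 1))
    base_var = n_total * (n_total + 1) / 12.0 - tie_term

    pairs = list(itertools.combinations(range(k), 2))
    raw = []
    for i, j in pairs:
        se = math.sqrt(base_var * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
        raw.append(2.0 * stats.norm.sf(abs(z)))
    corrected = multipletests(raw, method=correction)[1] if pairs else []

    mat = pd.DataFrame(np.eye(k), index=labels, columns=labels)
    for (i, j), p in zip(pairs, corrected):
        mat.iat[i, j] = mat.iat[j, i] = float(p)
    return mat


def ks_pairwise(
    groups: Sequence[Sequence[float]],
    labels: Sequence[str] | None = None,
    method: str = "auto",
) -> pd.DataFrame:
    """Pairwise two-sample two-sided Kolmogorov–Smirnov p-value matrix."""
    k = len(groups)
    if labels is None:
        labels = [f"group{i}" for i in range(k)]
    arrays = [np.asarray(g, float) for g in groups]
    if any(len(a) < 2 for a in arrays):
        raise ValueError("each group needs n >= 2")
    mat = pd.DataFrame(np.eye(k), index=labels, columns=labels)
    for i, j in itertools.combinations(range(k), 2):
        p = float(stats.ks_2samp(arrays[i], arrays[j], method=method).pvalue)
        mat.iat[i, j] = mat.iat[j, i] = p
    return mat


def compare_cohorts(
    feature_table: pd.DataFrame,
    cohort_column: str = "cohort",
    features: Sequence[str] = FEATURE_NAMES,
) -> pd.DataFrame:
    """Run the full nonparametric battery feature-by-feature.

    Returns a long frame with the Kruskal–Wallis H and p plus the pairwise
    Dunn (Holm-corrected) and K–S p-values for every cohort pair, and a
    ``dimensionless`` flag marking the features comparable across cohorts
    without units caveats.
    """
    cohorts = sorted(feature_table[cohort_column].unique())
    rows = []
    for feat in features:
        groups, labels = [], []
        for c in cohorts:
            v = feature_table.loc[feature_table[cohort_column] == c, feat]
            v = v[np.isfinite(v)].to_numpy()
            if len(v):
                groups.append(v)
                labels.append(str(c))
        if len(groups) < 2:
            continue
        row: dict[str, object] = {"feature": feat,
                                  "dimensionless": feat in DIMENSIONLESS}
        if len(groups) >= 3 and all(len(g) >= 5 for g in groups):
            row["kw_H"], row["kw_p"] = kruskal_wallis(groups)
        else:
            row["kw_H"] = row["kw_p"] = math.nan
        dunn = dunn_posthoc(groups, labels)
        ks = ks_pairwise(groups, labels)
        for a, b in itertools.combinations(labels, 2):
            row[f"dunn_p[{a}|{b}]"] = dunn.loc[a, b]
            row[f"ks_p[{a}|{b}]"] = ks.loc[a, b]
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class AgeRegressionResult:
    feature: str
    standardized_beta: float
    adjusted_r2: float
    p_value: float
    significant: bool
    n: int


def age_regressions(
    feature_table: pd.DataFrame,
    ages: pd.Series | Mapping[str, float],
    features: Sequence[str] = FEATURE_NAMES,
    alpha: float = BONFERRONI_ALPHA,
) -> list[AgeRegressionResult]:
    """Univariate OLS of each feature on standardized ordinal age.

    ``ages`` maps participant_id to an ordinal age value (e.g. a band
    midpoint in years). Age is z-scored before the regression, so the slope
    is the feature change per SD of age (the standardized beta); the
    overall-regression p-value is Bonferroni-flagged at ``alpha``
    (default 0.05/15).
    """
    import statsmodels.api as sm

    age_map = dict(ages) if not isinstance(ages, pd.Series) else ages.to_dict()
    age_vec = feature_table["participant_id"].astype(str).map(
        {str(k): v for k, v in age_map.items()})
    results = []
    for feat in features:
        y = feature_table[feat].to_numpy(dtype=float)
        x = age_vec.to_numpy(dtype=float)
        ok = np.isfinite(y) & np.isfinite(x)
        if ok.sum() < 10:
            raise ValueError(f"need >= 10 participants with age for {feat}")
        xs, ys = x[ok], y[ok]
        if np.std(xs) == 0:
            raise ValueError("zero age variance")
        zx = (xs - xs.mean()) / xs.std(ddof=1)
        model = sm.OLS(ys, sm.add_constant(zx)).fit()
        p = float(model.f_pvalue)
        results.append(AgeRegressionResult(
            feature=feat,
            standardized_beta=float(model.params[1]),
            adjusted_r2=float(model.rsquared_adj),
            p_value=p,
            significant=bool(p < alpha),
            n=int(ok.sum()),
        ))
    return results


def summaries_table(feature_table: pd.DataFrame,
                    cohort_column: str = "cohort",
                    features: Sequence[str] = FEATURE_NAMES) -> pd.DataFrame:
    """Feature-by-cohort summary frame (mean/SD/SEM/CI/median/IQR/n)."""
    rows = []
    for cohort, grp in feature_table.groupby(cohort_column, observed=True):
        for feat in features:
            v = grp[feat].to_numpy(dtype=float)
            v = v[np.isfinite(v)]
            if len(v) < 2:
                continue
            rows.append(feature_summary(v, str(cohort), feat).__dict__)
    return pd.DataFrame(rows)


def violin_plots(feature_table: pd.DataFrame, out_path,
                 cohort_column: str = "cohort",
                 features: Sequence[str] = FEATURE_NAMES) -> None:
    """Tile violin plots of the feature distributions per cohort (PNG/SVG)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    cohorts = sorted(feature_table[cohort_column].unique())
    ncols = 5
    nrows = int(np.ceil(len(features) / ncols))
    fig, axes = plt.subplots(nrows, ncols, figsize=(3.2 * ncols, 2.6 * nrows))
    for ax, feat in zip(np.ravel(axes), features):
        data = []
        for c in cohorts:
            v = feature_table.loc[feature_table[cohort_column] == c, feat]
            data.append(v[np.isfinite(v)].to_numpy())
        if all(len(d) > 1 for d in data):
            ax.violinplot(data, showmedians=True)
            ax.set_xticks(range(1, len(cohorts) + 1))
            ax.set_xticklabels([str(c) for c in cohorts], fontsize=7)
        ax.set_title(feat, fontsize=9)
    for ax in np.ravel(axes)[len(features):]:
        ax.axis("off")
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
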