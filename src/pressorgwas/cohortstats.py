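"""Clinical-feature hypothesis tests and comorbidity profiling.

Categorical features across response subgroups are compared by the Pearson
chi-square test (no continuity correction), continuous features by classic
one-way ANOVA, with a Bonferroni-adjusted significance threshold. Comorbid
conditions are ICD-9 codes truncated to their 3-digit class; a patient has
*reportable evidence* for a class only if it was coded on at least three
distinct dates. Classes prevalent in every subgroup are assembled into a
prevalence matrix and organized by agglomerative hierarchical clustering
(Euclidean distance, average linkage / UPGMA).
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist

__all__ = [
    "chi_square_test",
    "one_way_anova",
    "one_way_anova_summary",
    "welch_pairwise",
    "bonferroni",
    "truncate_icd",
    "reportable_conditions",
    "prevalence_matrix",
    "PrevalenceMatrix",
    "hierarchical_cluster",
]

_ICD_RE = re.compile(r"^([VE]?\d+)(?:\.(\d+))?$")


def chi_square_test(table) -> tuple[float, int, float]:
    """Pearson chi-square test of independence on an r x c count table.

    Returns (statistic, df, P) with statistic = sum (O-E)^2 / E,
    df = (r-1)(c-1), upper-tail P, and no continuity correction.
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.min() < 0:
        raise ValueError("need a 2-D table of nonnegative counts")
    if obs.sum() == 0:
        raise ValueError("empty table")
    if (obs.sum(axis=0) == 0).any() or (obs.sum(axis=1) == 0).any():
        raise ValueError("zero row or column margin")
    stat, p, df, _ = stats.chi2_contingency(obs, correction=False)
    return float(stat), int(df), float(p)


def one_way_anova(*groups) -> tuple[float, int, int, float]:
    """Classic (equal-variance) one-way ANOVA on raw per-group values.

    Returns (F, df_between, df_within, P).
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(len(a) < 2 for a in arrays):
        raise ValueError("each group needs n >= 2")
    summaries = [(len(a), a.mean(), a.std(ddof=1)) for a in arrays]
    return one_way_anova_summary(summaries)


def one_way_anova_summary(
    summaries: list[tuple[int, float, float]]
) -> tuple[float, int, int, float]:
    """One-way ANOVA from per-group (n, mean, sd) summaries.

    Algebraically identical to the raw-data decomposition: the between-group
    sum of squares uses the grand mean, the within-group sum of squares is
    sum (n_i - 1) sd_i^2.
    """
    if len(summaries) < 2:
        raise ValueError("need at least 2 groups")
    n = np.array([s[0] for s in summaries], dtype=float)
    m = np.array([s[1] for s in summaries], dtype=float)
    sd = np.array([s[2] for s in summaries], dtype=float)
    if (n < 2).any():
        raise ValueError("each group needs n >= 2")
    grand = float((n * m).sum() / n.sum())
    ss_between = float((n * (m - grand) ** 2).sum())
    ss_within = float(((n - 1) * sd**2).sum())
    df1 = len(summaries) - 1
    df2 = int(n.sum()) - len(summaries)
    if ss_within == 0:
        if ss_between == 0:
            return 0.0, df1, df2, 1.0
        raise ValueError("zero within-group variance in all groups")
    f = (ss_between / df1) / (ss_within / df2)
    return float(f), df1, df2, float(stats.f.sf(f, df1, df2))


def welch_pairwise(
    summaries: dict[str, tuple[int, float, float]]
) -> pd.DataFrame:
    """Welch (unequal-variance) t-tests for every pair of groups.

    A descriptive companion to the omnibus ANOVA; this package's own choice
    of pairwise procedure, computed from (n, mean, sd) summaries.
    """
    rows = []
    names = list(summaries)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            na, ma, sa = summaries[a]
            nb, mb, sb = summaries[b]
            va, vb = sa**2 / na, sb**2 / nb
            t = (ma - mb) / np.sqrt(va + vb)
            df = (va + vb) ** 2 / (va**2 / (na - 1) + vb**2 / (nb - 1))
            p = 2 * stats.t.sf(abs(t), df)
            rows.append({"group1": a, "group2": b, "t": t, "df": df, "p": p})
    return pd.DataFrame(rows)


def bonferroni(alpha: float, m: int) -> float:
    """Bonferroni-adjusted per-test significance threshold alpha / m."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m


def truncate_icd(code: str) -> str:
    """Truncate an ICD-9 code to its 3-digit disease class.

    The class is the substring before the decimal point; V- and E-prefixed
    codes keep their letter (``V45.1`` -> ``V45``).
    """
    code = code.strip()
    m = _ICD_RE.match(code)
    if not m:
        raise ValueError(f"malformed ICD-9 code: {code!r}")
    return m.group(1)


def reportable_conditions(
    icd_events: pd.DataFrame, min_dates: int = 3
) -> dict[str, set[str]]:
    """Map each patient to the 3-digit classes coded on >= min_dates distinct dates.

    ``icd_events`` needs columns patient_id, code, date. Repeats on the same
    date count once.
    """
    if icd_events.empty:
        return {}
    df = icd_events.copy()
    df["cls"] = df["code"].map(truncate_icd)
    counts = df.groupby(["patient_id", "cls"])["date"].nunique()
    qualifying = counts[counts >= min_dates]
    out: dict[str, set[str]] = {}
    for (pid, cls) in qualifying.index:
        out.setdefault(pid, set()).add(cls)
    return out


@dataclass
class PrevalenceMatrix:
    """Groups x disease-classes prevalence with the underlying counts."""

    prevalence: pd.DataFrame  # groups x classes, fractions
    numerators: pd.DataFrame
    group_sizes: pd.Series


def prevalence_matrix(
    conditions: dict[str, set[str]],
    labels: pd.Series,
    min_prev: float = 0.005,
) -> PrevalenceMatrix:
    """Per-group prevalence of each condition class, keeping classes whose
    prevalence is >= ``min_prev`` in *every* group.

    ``labels`` maps patient_id -> group label and defines the denominators;
    patients without any reportable condition still count in them.
    """
    groups = labels.unique()
    sizes = labels.value_counts()
    if (sizes == 0).any() or len(groups) == 0:
        raise ValueError("empty group")
    all_classes = sorted({c for s in conditions.values() for c in s})
    num = pd.DataFrame(0, index=sorted(groups), columns=all_classes, dtype=int)
    for pid, classes in conditions.items():
        if pid not in labels.index:
            continue
        g = labels.loc[pid]
        for c in classes:
            num.loc[g, c] += 1
    prev = num.div(sizes.reindex(num.index), axis=0)
    keep = [c for c in all_classes if (prev[c] >= min_prev).all()]
    return PrevalenceMatrix(
        prevalence=prev[keep],
        numerators=num[keep],
        group_sizes=sizes.reindex(num.index),
    )


def hierarchical_cluster(
    matrix: pd.DataFrame, metric: str = "euclidean", method: str = "average"
) -> tuple[np.ndarray, list]:
    """Agglomerative clustering of the matrix rows (UPGMA by default).

    Returns the scipy linkage matrix and the dendrogram leaf order as row
    labels. Ties in merge distance resolve deterministically toward lower
    indices (scipy's stable ordering).
    """
    X = matrix.to_numpy(dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 rows")
    if not np.isfinite(X).all():
        raise ValueError("non-finite entries")
    Z = linkage(pdist(X, metric=metric), method=method)
    order = [matrix.index[i] for i in leaves_list(Z)]
    return Z, order
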