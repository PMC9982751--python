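"""Cohort statistics for graded morphometry tables.

Wraps the classical tests used for eye-level vascular cohorts: per-grade
mean +/- SD summaries, one-way ANOVA across grades, Pearson chi-square for
categorical composition, pairwise grade comparisons (Welch t by default,
Bonferroni/Tukey selectable), Pearson correlations of morphometry with
covariates, and paired t-tests for matched case/control designs.  Eyes are
the analysis unit; within-subject correlation between fellow eyes is
deliberately not modeled (documented limitation of eye-level analyses).
"""

from __future__ import annotations

import warnings
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import MYOPIA_GRADES

#: Morphometry columns in a cohort table.
METRIC_COLUMNS = ("vessel_angle_deg", "df", "vessel_density_pct", "branch_count")
#: Covariates correlated with morphometry.
COVARIATE_COLUMNS = ("AL_mm", "BCVA_logMAR", "age")


def summarize_by_grade(cohort: pd.DataFrame, metric: str,
                       grades: Sequence[str] = MYOPIA_GRADES) -> pd.DataFrame:
    """Per-grade (n, mean, sd) summary of one metric (sample SD, ddof=1)."""
    rows = []
    for g in grades:
        vals = cohort.loc[cohort["grade"] == g, metric].to_numpy(dtype=float)
        if vals.size < 2:
            warnings.warn(f"grade {g} has < 2 rows; omitted from summary",
                          stacklevel=2)
            continue
        rows.append({"grade": g, "n": int(vals.size),
                     "mean": float(vals.mean()),
                     "sd": float(vals.std(ddof=1))})
    return pd.DataFrame(rows).set_index("grade")


def anova_oneway(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Classical one-way ANOVA F and p over >= 2 groups of n >= 2."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2 or any(a.size < 2 for a in arrays):
        raise ValueError("need >= 2 groups with n >= 2 each")
    if all(a.var() == 0 for a in arrays):
        means = [a.mean() for a in arrays]
        if np.ptp(means) == 0:
            return 0.0, 1.0
        warnings.warn("zero within-group variance with unequal means; "
                      "F is infinite, p reported as 0", stacklevel=2)
        return float("inf"), 0.0
    f, p = sps.f_oneway(*arrays)
    return float(f), float(p)


def chi_square_2xk(table) -> tuple[float, float]:
    """Pearson chi-square (no continuity correction) on a 2 x k count table."""
    table = np.asarray(table, dtype=float)
    if table.ndim != 2:
        raise ValueError("table must be 2-D")
    if (table < 0).any() or not np.allclose(table, np.round(table)):
        raise ValueError("counts must be non-negative integers")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("zero marginal in contingency table")
    chi2, p, _, _ = sps.chi2_contingency(table, correction=False)
    return float(chi2), float(p)


def pairwise_grade_comparisons(cohort: pd.DataFrame, metric: str,
                               method: str = "welch",
                               grades: Sequence[str] = MYOPIA_GRADES
                               ) -> pd.DataFrame:
    """All 10 grade-pair p-values as a lower-triangular matrix.

    Rows C1..C4, columns C0..C3, NaN above the diagonal — the layout of a
    pairwise-comparison table.  ``method``: ``welch`` (unpaired two-sided
    Welch t, uncorrected — the default because the multiplicity handling
    of such published tables is rarely stated), ``bonferroni`` (Welch p
    x 10, capped at 1), or ``tukey`` (Tukey HSD on all five groups).
    """
    grades = list(grades)
    samples = {}
    for g in grades:
        v = cohort.loc[cohort["grade"] == g, metric].to_numpy(dtype=float)
        if v.size < 2:
            raise ValueError(f"grade {g} missing or has < 2 rows")
        samples[g] = v

    mat = pd.DataFrame(np.nan, index=grades[1:], columns=grades[:-1])
    if method == "tukey":
        res = sps.tukey_hsd(*[samples[g] for g in grades])
        for i, j in combinations(range(len(grades)), 2):
            mat.loc[grades[j], grades[i]] = float(res.pvalue[i, j])
        return mat
    if method not in ("welch", "bonferroni"):
        raise ValueError(f"unknown method {method!r}")
    n_pairs = len(grades) * (len(grades) - 1) // 2
    for gi, gj in combinations(grades, 2):
        if np.array_equal(samples[gi], samples[gj]):
            p = 1.0
        else:
            p = float(sps.ttest_ind(samples[gi], samples[gj],
                                    equal_var=False).pvalue)
        if method == "bonferroni":
            p = min(1.0, p * n_pairs)
        mat.loc[gj, gi] = p
    return mat


def correlate(cohort: pd.DataFrame, covariate: str, metric: str
              ) -> tuple[float, float]:
    """Pearson r and two-sided p between a covariate and a metric."""
    x = cohort[covariate].to_numpy(dtype=float)
    y = cohort[metric].to_numpy(dtype=float)
    if x.size < 3:
        raise ValueError("need n >= 3 for a correlation")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in correlation input")
    if x.var() == 0 or y.var() == 0:
        raise ValueError("zero variance: correlation undefined")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def correlation_table(cohort: pd.DataFrame,
                      covariates: Sequence[str] = COVARIATE_COLUMNS,
                      metrics: Sequence[str] = METRIC_COLUMNS) -> pd.DataFrame:
    """All (covariate, metric) Pearson r and p, one row per metric."""
    rows = []
    for metric in metrics:
        row: dict = {"metric": metric}
        for cov in covariates:
            r, p = correlate(cohort, cov, metric)
            row[f"r_{cov}"] = r
            row[f"p_{cov}"] = p
        rows.append(row)
    return pd.DataFrame(rows).set_index("metric")


def paired_compare(paired: pd.DataFrame, metric: str,
                   case: str = "case", control: str = "control"
                   ) -> tuple[float, float]:
    """Two-sided paired t-test on matched case - control differences.

    ``paired`` is long-format with columns ``match_id``, ``arm`` and the
    metric; arms must align one-to-one on ``match_id``.
    """
    wide = paired.pivot(index="match_id", columns="arm", values=metric)
    if case not in wide.columns or control not in wide.columns:
        raise ValueError(f"arms {case!r}/{control!r} not both present")
    if wide[[case, control]].isna().any().any():
        raise ValueError("unmatched rows in paired cohort")
    d = (wide[case] - wide[control]).to_numpy(dtype=float)
    if d.size < 2:
        raise ValueError("need >= 2 pairs")
    if np.ptp(d) == 0:
        if d[0] == 0:
            return 0.0, 1.0
        warnings.warn("constant nonzero differences: t is infinite, p "
                      "reported as 0", stacklevel=2)
        return float(np.inf) * np.sign(d[0]), 0.0
    t, p = sps.ttest_rel(wide[case], wide[control])
    return float(t), float(p)


def grade_table(cohort: pd.DataFrame,
                metrics: Sequence[str] = METRIC_COLUMNS,
                covariates: Sequence[str] = ("age", "BCVA_logMAR", "AL_mm"),
                grades: Sequence[str] = MYOPIA_GRADES) -> pd.DataFrame:
    """Grade-by-characteristic summary with the one-way ANOVA p column."""
    rows = []
    for col in list(covariates) + list(metrics):
        row: dict = {"characteristic": col}
        groups = []
        for g in grades:
            v = cohort.loc[cohort["grade"] == g, col].to_numpy(dtype=float)
            groups.append(v)
            row[g] = f"{v.mean():.2f} ± {v.std(ddof=1):.2f}"
        _, p = anova_oneway(groups)
        row["p"] = p
        rows.append(row)
    return pd.DataFrame(rows).set_index("characteristic")
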