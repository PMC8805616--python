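"""Outlier handling, group summaries and statistical comparisons.

Conventions mirrored here: values farther than 1.5 interquartile ranges
from the 25th/75th percentile are removed (one pass, linear-interpolation
quartiles); summaries are mean +/- SEM; group comparisons dispatch to
one-way ANOVA, two-way ANOVA (statsmodels) or Kruskal-Wallis, each with
Bonferroni-corrected pairwise post hoc tests.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import DataError, MeasurementTable, warn


def remove_outliers(values: Sequence[float]):
    """Single-pass interquartile fence: keep Q1 - 1.5*IQR <= v <= Q3 + 1.5*IQR.

    Quartiles use linear interpolation.  Fewer than 4 values are returned
    unchanged with a warning.  Returns ``(kept, removed)`` arrays.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 4:
        warn("fewer than 4 values; outlier rule not applied")
        return v, np.array([])
    q1, q3 = np.percentile(v, [25, 75])
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    keep = (v >= lo) & (v <= hi)
    return v[keep], v[~keep]


@dataclass
class GroupSummary:
    keys: dict
    n: int
    mean: float
    sem: Optional[float]
    removed: np.ndarray = field(default_factory=lambda: np.array([]))


def summarize(values: Sequence[float], keys: Optional[dict] = None,
              outlier_removal: bool = True) -> GroupSummary:
    """Mean +/- SEM of one group cell, after optional outlier removal."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise DataError("empty group")
    removed = np.array([])
    if outlier_removal:
        v, removed = remove_outliers(v)
    sem = float(np.std(v, ddof=1) / np.sqrt(v.size)) if v.size > 1 else None
    if sem is None:
        warn("single value; SEM undefined")
    return GroupSummary(keys or {}, int(v.size), float(np.mean(v)), sem,
                        removed)


def bonferroni(p_values: Sequence[float]) -> np.ndarray:
    """Multiply by the number of comparisons, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    return np.minimum(p * p.size, 1.0)


@dataclass
class ComparisonResult:
    test: str
    statistic: float
    df: tuple
    p_value: float
    pairwise: pd.DataFrame  # columns: a, b, p_raw, p_adj


def compare_groups(df: pd.DataFrame, response: str, factors: Sequence[str],
                   kind: str = "anova") -> ComparisonResult:
    """Dispatch a group comparison.

    ``kind``: 'anova' (one-way, or two-way with two factors),
    'kruskal' (rank-based one-way).  Pairwise post hoc tests over levels
    of the first factor are Bonferroni-adjusted.
    """
    factors = list(factors)
    if not factors or response not in df.columns:
        raise DataError("design must name a response and >= 1 factor")
    levels = sorted(df[factors[0]].dropna().unique())
    if len(levels) < 2:
        raise DataError("need >= 2 groups to compare")
    groups = [df.loc[df[factors[0]] == g, response].dropna().to_numpy()
              for g in levels]

    if kind == "kruskal":
        stat, p = sps.kruskal(*groups)
        test, dfree = "kruskal-wallis", (len(groups) - 1,)
        pair_test = lambda a, b: sps.mannwhitneyu(a, b,
                                                  alternative="two-sided")[1]
    elif len(factors) == 2:
        import statsmodels.api as sm
        import statsmodels.formula.api as smf
        d = df.rename(columns={response: "y", factors[0]: "f1",
                               factors[1]: "f2"})
        model = smf.ols("y ~ C(f1) * C(f2)", data=d).fit()
        table = sm.stats.anova_lm(model, typ=2)
        stat = float(table.loc["C(f1)", "F"])
        p = float(table.loc["C(f1)", "PR(>F)"])
        test = "two-way anova"
        dfree = (int(table.loc["C(f1)", "df"]),
                 int(table.loc["Residual", "df"]))
        pair_test = lambda a, b: sps.ttest_ind(a, b)[1]
    else:
        stat, p = sps.f_oneway(*groups)
        test = "one-way anova"
        dfree = (len(groups) - 1, sum(len(g) for g in groups) - len(groups))
        pair_test = lambda a, b: sps.ttest_ind(a, b)[1]

    pairs = list(itertools.combinations(range(len(levels)), 2))
    raw = [pair_test(groups[i], groups[j]) for i, j in pairs]
    adj = bonferroni(raw)
    pairwise = pd.DataFrame({"a": [levels[i] for i, _ in pairs],
                             "b": [levels[j] for _, j in pairs],
                             "p_raw": raw, "p_adj": adj})
    return ComparisonResult(test, float(stat), dfree, float(p), pairwise)


_COUNT_RE = re.compile(r"^\s*(\d+)\s*/\s*(\d+)\s*$")


def check_count_percentage(counts: str, stated_pct: float,
                           decimals: int = 1, tol: float = 0.05) -> bool:
    """True when a printed 'n/N' count string is consistent with its stated
    percentage at the printed precision."""
    from .synaptic import proportion_responsive
    m = _COUNT_RE.match(counts)
    if not m:
        raise DataError(f"malformed count string {counts!r}")
    n, total = int(m.group(1)), int(m.group(2))
    return abs(proportion_responsive(n, total, decimals) - stated_pct) <= tol


def build_report(measurements: MeasurementTable,
                 count_claims: Optional[pd.DataFrame] = None,
                 outlier_removal: bool = True) -> dict:
    """Assemble group-summary tables and comparisons per variable.

    Returns a dict with a 'summary' DataFrame (group means +/- SEM per
    (variable, group, age, layer) cell), a 'tests' DataFrame (per-variable
    group comparison within each age/layer stratum), and
    'inconsistencies' listing count/percentage claims that do not
    reproduce from their own counts.
    """
    df = measurements.included()
    rows, tests = [], []
    for (var, age, layer), sub in df.groupby(["variable", "age", "layer"]):
        for grp, cell in sub.groupby("group"):
            s = summarize(cell["value"], outlier_removal=outlier_removal)
            rows.append({"variable": var, "age": age, "layer": layer,
                         "group": grp, "n": s.n, "mean": s.mean,
                         "sem": s.sem, "n_removed": s.removed.size})
        if sub["group"].nunique() >= 2 and len(sub) >= 4:
            try:
                res = compare_groups(sub, "value", ["group"])
                tests.append({"variable": var, "age": age, "layer": layer,
                              "test": res.test, "statistic": res.statistic,
                              "p_value": res.p_value})
            except (DataError, ValueError) as e:
                warn(f"{var}/{age}/{layer}: comparison skipped ({e})")
    inconsistencies = []
    if count_claims is not None:
        for _, row in count_claims.iterrows():
            ok = check_count_percentage(row["counts"], row["stated_pct"],
                                        int(row.get("decimals", 1)))
            if not ok:
                inconsistencies.append(dict(row))
    return {"summary": pd.DataFrame(rows), "tests": pd.DataFrame(tests),
            "inconsistencies": pd.DataFrame(inconsistencies)}
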