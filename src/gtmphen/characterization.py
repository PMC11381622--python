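"""Post-hoc phenotype characterisation: per-group summaries and hypothesis
tests.

Continuous variables are summarised by median and interquartile range and
compared across phenotypes with the Kruskal-Wallis test (midrank ties
correction, chi-squared reference with g-1 df); categorical and one-hot
encoded ordinal variables are summarised by counts/percentages and compared
with Pearson's chi-squared test (no continuity correction).  Raw two-sided
p-values are flagged at 0.05 with no multiple-testing adjustment by default,
mirroring the procedure the pipeline reproduces; Benjamini-Hochberg is
available but off by default.

Quantiles use linear interpolation (type 7), the numpy/pandas default.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import CohortTable, VType

__all__ = ["summarize", "compare"]

ALPHA = 0.05


def _check_labels(table: CohortTable, labels: Sequence) -> np.ndarray:
    labels = np.asarray(labels)
    if labels.shape[0] != table.n_subjects:
        raise ValueError(
            f"labels length {labels.shape[0]} != number of subjects {table.n_subjects}"
        )
    return labels


def summarize(table: CohortTable, labels: Sequence) -> pd.DataFrame:
    """Tidy per-group summary table.

    One row per (variable, group) for continuous variables (median, Q1, Q3,
    n) and per (variable, level, group) for categorical/ordinal ones (count,
    percent, n).  Missing values are excluded per variable, with the
    contributing n reported.
    """
    labels = _check_labels(table, labels)
    groups = sorted(pd.unique(labels), key=str)
    rows = []
    for meta in table.variables:
        col = table.data[meta.name]
        for g in groups:
            vals = col[labels == g].dropna()
            if meta.vtype is VType.CONTINUOUS:
                if len(vals):
                    q1, med, q3 = np.quantile(vals.astype(float), [0.25, 0.5, 0.75])
                else:
                    q1 = med = q3 = np.nan
                rows.append({"variable": meta.name, "vtype": meta.vtype.value,
                             "group": g, "level": "", "n": len(vals),
                             "median": med, "q1": q1, "q3": q3,
                             "count": np.nan, "percent": np.nan})
            else:
                counts = vals.value_counts()
                for lev in sorted(counts.index, key=str):
                    c = int(counts[lev])
                    rows.append({"variable": meta.name, "vtype": meta.vtype.value,
                                 "group": g, "level": str(lev), "n": len(vals),
                                 "median": np.nan, "q1": np.nan, "q3": np.nan,
                                 "count": c,
                                 "percent": 100.0 * c / len(vals) if len(vals) else np.nan})
    return pd.DataFrame(rows)


def compare(table: CohortTable, labels: Sequence, adjust: bool = False) -> pd.DataFrame:
    """Between-phenotype tests, one row per variable.

    Continuous -> Kruskal-Wallis H (df = groups - 1); categorical/ordinal ->
    chi-squared on the level x group contingency table.  Variables constant
    across all subjects are skipped and reported with test "NA".  With
    ``adjust=True`` a ``p_adjusted`` (Benjamini-Hochberg) column is added;
    the significance flag always refers to the raw p-value at 0.05.
    """
    labels = _check_labels(table, labels)
    groups = sorted(pd.unique(labels), key=str)
    if len(groups) < 2:
        raise ValueError("need at least two non-empty groups")
    rows = []
    for meta in table.variables:
        col = table.data[meta.name]
        obs_mask = col.notna().to_numpy()
        vals, labs = col[obs_mask], labels[obs_mask]
        nonempty = [g for g in groups if (labs == g).sum() > 0]
        if len(pd.unique(vals)) <= 1 or len(nonempty) < 2:
            rows.append({"variable": meta.name, "test": "NA", "statistic": np.nan,
                         "df": np.nan, "p_value": np.nan, "significant": False})
            continue
        if meta.vtype is VType.CONTINUOUS:
            samples = [vals[labs == g].astype(float).to_numpy() for g in nonempty]
            stat, p = stats.kruskal(*samples)
            test, df = "kruskal-wallis", len(nonempty) - 1
        else:
            contingency = pd.crosstab(vals.astype(str), labs).to_numpy()
            res = stats.chi2_contingency(contingency, correction=False)
            stat, p, df = res[0], res[1], res[2]
            test = "chi-squared"
        rows.append({"variable": meta.name, "test": test, "statistic": float(stat),
                     "df": int(df), "p_value": float(p),
                     "significant": bool(p < ALPHA)})
    out = pd.DataFrame(rows)
    if adjust:
        out["p_adjusted"] = _benjamini_hochberg(out["p_value"].to_numpy())
    return out


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    adj = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    ps = p[ok]
    m = ps.size
    order = np.argsort(ps)
    ranked = ps[order] * m / (np.arange(m) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    adj[ok] = out
    return adj
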