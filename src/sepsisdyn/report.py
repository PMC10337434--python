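"""Phenotype characterization tables and cohort summaries.

Continuous variables are summarized as median (25-75% IQR) per phenotype
with Kruskal-Wallis rank-sum tests; binary variables as n (%) per
phenotype with Pearson chi-square tests (no continuity correction — these
are 4-group tables). Percentages are always derived from the stored raw
counts so every printed figure is recomputable.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import OUTCOMES, CohortBundle

__all__ = [
    "characterize",
    "summarize_outcomes",
    "missingness_by_cluster",
]


def _is_binary(values: np.ndarray) -> bool:
    u = np.unique(values[~np.isnan(values)])
    return u.size <= 2 and np.all(np.isin(u, (0.0, 1.0)))


def _continuous_row(values_by_group: list[np.ndarray], pooled: np.ndarray):
    cells = {}
    for g, vals in enumerate(values_by_group, start=1):
        if vals.size:
            q1, med, q3 = np.percentile(vals, [25, 50, 75])
            cells[f"P{g}"] = f"{med:.2f} ({q1:.2f}-{q3:.2f})"
        else:
            cells[f"P{g}"] = ""
    q1, med, q3 = (np.percentile(pooled, [25, 50, 75]) if pooled.size
                   else (np.nan,) * 3)
    cells["pooled"] = f"{med:.2f} ({q1:.2f}-{q3:.2f})" if pooled.size else ""
    groups = [v for v in values_by_group if v.size]
    if len(groups) >= 2:
        try:
            stat, p = stats.kruskal(*groups)
        except ValueError:   # all values identical
            p = np.nan
        cells["test"] = "kruskal-wallis"
        cells["p_value"] = p
    else:
        cells["test"] = "n/a"
        cells["p_value"] = np.nan
    return cells


def _binary_row(values_by_group: list[np.ndarray], pooled: np.ndarray):
    cells = {}
    table = []
    for g, vals in enumerate(values_by_group, start=1):
        n, c = vals.size, int(np.nansum(vals))
        cells[f"P{g}_count"] = c
        cells[f"P{g}_n"] = n
        cells[f"P{g}"] = f"{c} ({100.0 * c / n:.2f})" if n else ""
        if n:
            table.append([c, n - c])
    c, n = int(np.nansum(pooled)), pooled.size
    cells["pooled"] = f"{c} ({100.0 * c / n:.2f})" if n else ""
    tab = np.array(table)
    if len(tab) >= 2 and tab.sum(axis=0).min() > 0:
        stat, p, _, _ = stats.chi2_contingency(tab, correction=False)
        cells["test"] = "chi-square"
        cells["p_value"] = p
    else:
        cells["test"] = "n/a"
        cells["p_value"] = np.nan
    return cells


def characterize(bundle: CohortBundle, labels: pd.Series,
                 horizon_hours: float = 6.0) -> pd.DataFrame:
    """Per-phenotype characterization table (variables and outcomes).

    ``labels`` maps patient_id -> phenotype (1..k). Dynamic variables are
    summarized by each patient's median raw value within the first
    ``horizon_hours``; statics and outcomes are taken as stored. Phenotypes
    with zero patients yield empty columns and skipped tests.
    """
    labels = pd.Series(labels)
    k = int(labels.max()) if len(labels) else 0
    ids_by_group = [labels.index[labels == g] for g in range(1, k + 1)]
    if any(len(ids) == 0 for ids in ids_by_group):
        warnings.warn("one or more phenotypes have zero patients; "
                      "tests skipped where undefined")

    rows = {}

    meas = bundle.measurements
    meas = meas[meas["hours_since_triage"] <= horizon_hours]
    per_patient = meas.groupby(["variable", "patient_id"])["value"].median()
    for var in per_patient.index.get_level_values(0).unique():
        series = per_patient.loc[var]
        groups = [series.reindex(ids).dropna().to_numpy() for ids in ids_by_group]
        pooled = series.reindex(labels.index).dropna().to_numpy()
        rows[var] = _continuous_row(groups, pooled) | {"kind": "continuous"}

    statics = bundle.statics.pivot_table(index="patient_id", columns="variable",
                                         values="value", aggfunc="first")
    for var in statics.columns:
        col = statics[var].reindex(labels.index)
        vals = col.to_numpy(float)
        groups = [col.reindex(ids).dropna().to_numpy(float) for ids in ids_by_group]
        pooled = col.dropna().to_numpy(float)
        if _is_binary(vals):
            rows[var] = _binary_row(groups, pooled) | {"kind": "binary"}
        else:
            rows[var] = _continuous_row(groups, pooled) | {"kind": "continuous"}

    out = bundle.outcomes.set_index("patient_id")
    for var in OUTCOMES:
        col = out[var].reindex(labels.index)
        groups = [col.reindex(ids).dropna().to_numpy(float) for ids in ids_by_group]
        rows[var] = _binary_row(groups, col.dropna().to_numpy(float)) | {
            "kind": "outcome"
        }

    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "variable"
    return table


def summarize_outcomes(outcomes: pd.DataFrame) -> dict:
    """Combined and per-outcome counts/percents (percent to one decimal).

    The headline quantity is combined in-hospital mortality or transition
    to hospice; mortality and hospice are mutually exclusive events so the
    combined count is the sum of the two counts.
    """
    n = len(outcomes)
    summary = {"n": n, "outcomes": {}}
    for col in outcomes.columns:
        if col == "patient_id":
            continue
        c = int(outcomes[col].sum())
        summary["outcomes"][col] = {
            "count": c,
            "percent": round(100.0 * c / n, 1) if n else 0.0,
        }
    mort = outcomes["mortality"] if "mortality" in outcomes else pd.Series(0, index=outcomes.index)
    hosp = outcomes["hospice"] if "hospice" in outcomes else pd.Series(0, index=outcomes.index)
    combined = int(((mort == 1) | (hosp == 1)).sum()) if n else 0
    summary["mortality_or_hospice"] = {
        "count": combined,
        "percent": round(100.0 * combined / n, 1) if n else 0.0,
    }
    return summary


def missingness_by_cluster(mask: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    """Fractions of observed / held / mean-imputed entries per phenotype.

    ``mask`` is a :class:`FeatureMatrix` mask (patients x variables, codes
    0=observed, 1=held, 2=mean-imputed); the returned frame is indexed by
    (phenotype, variable) with one column per code fraction plus
    ``measured`` (observed or held: the variable was seen at least once by
    the horizon).
    """
    labels = pd.Series(labels)
    mask = mask.reindex(labels.index)
    records = []
    for g in sorted(labels.unique()):
        sub = mask[labels == g]
        n = len(sub)
        for var in mask.columns:
            col = sub[var].to_numpy()
            obs = float((col == 0).mean()) if n else np.nan
            held = float((col == 1).mean()) if n else np.nan
            imp = float((col == 2).mean()) if n else np.nan
            records.append(
                {
                    "phenotype": int(g),
                    "variable": var,
                    "observed": obs,
                    "held": held,
                    "mean_imputed": imp,
                    "measured": obs + held if n else np.nan,
                }
            )
    return pd.DataFrame.from_records(records).set_index(["phenotype", "variable"])
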