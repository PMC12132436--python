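"""Cell-composition testing between conditions.

A global Pearson chi-square over the full cluster x condition table asks
whether composition differs at all; per-cluster tests then decompose the
shift by collapsing each cluster against all others into a 2x2 table, with
BH correction across clusters. No continuity correction is applied by
default, matching the global test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import bh_adjust


@dataclass
class ChisqResult:
    chi2: float
    df: int
    p_value: float
    low_expected: bool  # any expected count below 5


@dataclass
class CompositionResult:
    global_test: ChisqResult
    per_cluster: pd.DataFrame


def _as_table(table) -> pd.DataFrame:
    tab = pd.DataFrame(table)
    arr = tab.to_numpy()
    if arr.size == 0 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError("composition table needs at least 2 rows and 2 columns")
    if np.any(arr < 0) or not np.allclose(arr, np.round(arr)):
        raise ValueError("composition table must hold non-negative integer counts")
    return tab


def chisq_global(table, correction: bool = False) -> ChisqResult:
    """Pearson chi-square of homogeneity on a cluster x condition table."""
    tab = _as_table(table)
    arr = tab.to_numpy(dtype=float)
    row_sums, col_sums = arr.sum(axis=1), arr.sum(axis=0)
    if np.any(row_sums == 0) or np.any(col_sums == 0):
        empty_rows = list(tab.index[row_sums == 0])
        empty_cols = list(tab.columns[col_sums == 0])
        raise ValueError(
            f"zero margin: empty rows {empty_rows}, empty columns {empty_cols}"
        )
    chi2, p, df, expected = stats.chi2_contingency(arr, correction=correction)
    low = bool(np.any(expected < 5))
    if low:
        warnings.warn("expected counts below 5; chi-square approximation is weak",
                      stacklevel=2)
    return ChisqResult(chi2=float(chi2), df=int(df), p_value=float(p), low_expected=low)


def pairwise_proportions(table, correction: bool = False) -> CompositionResult:
    """Global test plus per-cluster cluster-vs-rest 2x2 chi-square tests.

    Requires exactly two conditions (columns). Clusters absent from both
    conditions are skipped with a reason; BH is applied across the clusters
    actually tested.
    """
    tab = _as_table(table)
    if tab.shape[1] != 2:
        raise ValueError("pairwise proportions need exactly 2 conditions")
    global_res = chisq_global(tab, correction=correction)
    col_tot = tab.to_numpy(dtype=float).sum(axis=0)

    rows = []
    for cluster, counts in tab.iterrows():
        c = counts.to_numpy(dtype=float)
        if c.sum() == 0:
            rows.append((cluster, np.nan, np.nan, np.nan, np.nan, "absent"))
            continue
        two_by_two = np.array([c, col_tot - c])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            chi2, p, _, _ = stats.chi2_contingency(two_by_two, correction=correction)
        rows.append((cluster, c[0] / col_tot[0], c[1] / col_tot[1],
                     float(chi2), float(p), ""))

    per = pd.DataFrame(
        rows,
        columns=["cluster", f"prop_{tab.columns[0]}", f"prop_{tab.columns[1]}",
                 "chi2", "p", "flag"],
    )
    per["q"] = np.nan
    ok = per["p"].notna()
    if ok.any():
        per.loc[ok, "q"] = bh_adjust(per.loc[ok, "p"].to_numpy())
    return CompositionResult(global_test=global_res, per_cluster=per)


def composition_table(calls: pd.DataFrame, ds) -> pd.DataFrame:
    """Cell-type x condition count table from annotation calls."""
    df = pd.DataFrame({"call": calls["call"].to_numpy(),
                       "condition": ds.cells["condition"].to_numpy()})
    return df.groupby(["call", "condition"], observed=True).size().unstack(fill_value=0)
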