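"""Two-group differential expression: Wilcoxon rank-sum, average log2
fold-change and Benjamini-Hochberg correction.

Two named selection regimes are shipped. ``cosmx`` calls a gene significant
at adjusted p < 0.05 with no fold-change floor, the convention for targeted
imaging panels where effect sizes are compressed. ``parse`` additionally
requires |avg log2FC| >= 0.26, the common whole-transcriptome droplet/split
-pool convention; ``parse_strict`` (adjusted p < 0.01, fold change > 1.5,
i.e. |avg log2FC| >= log2 1.5) is provided as a stricter preset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

#: regime name -> (alpha on adjusted p, |avg log2FC| floor)
DE_REGIMES: dict[str, tuple[float, float]] = {
    "cosmx": (0.05, 0.0),
    "parse": (0.05, 0.26),
    "parse_strict": (0.01, float(np.log2(1.5))),
}

EXACT_MAX_N = 16


@dataclass
class WilcoxonResult:
    statistic: float
    p_value: float
    method: str  # "exact" | "asymptotic" | "degenerate"


def wilcoxon_test(x: np.ndarray, y: np.ndarray) -> WilcoxonResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) test.

    Uses the exact null distribution when the combined sample is small
    (<= 16) and tie-free, otherwise the normal approximation with tie and
    continuity corrections. Identical constant samples get p = 1 by
    convention.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        return WilcoxonResult(statistic=len(x) * len(y) / 2.0, p_value=1.0,
                              method="degenerate")
    no_ties = len(np.unique(pooled)) == len(pooled)
    if len(pooled) <= EXACT_MAX_N and no_ties:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        return WilcoxonResult(float(res.statistic), float(res.pvalue), "exact")
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method="asymptotic", use_continuity=True
    )
    return WilcoxonResult(float(res.statistic), float(res.pvalue), "asymptotic")


def avg_log2fc(x_norm: np.ndarray, y_norm: np.ndarray, pseudo: float = 1e-9) -> float:
    """Average log2 fold-change of group 1 over group 2.

    Computed on the back-transformed normalized scale:
    log2((mean expm1(x) + pseudo) / (mean expm1(y) + pseudo)).
    """
    mx = float(np.mean(np.expm1(np.asarray(x_norm, dtype=float))))
    my = float(np.mean(np.expm1(np.asarray(y_norm, dtype=float))))
    return float(np.log2((mx + pseudo) / (my + pseudo)))


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def run_de(
    ds,
    groups: np.ndarray | pd.Series,
    regime: str = "cosmx",
    pseudo: float = 1e-9,
) -> pd.DataFrame:
    """Per-gene DE between two groups of cells on the normalized layer.

    ``groups`` is a per-cell binary label aligned to the dataset (bool, 0/1,
    or two string labels; group 1 = the lexicographically later label, so
    e.g. "mct8" vs "control" reports mct8-relative fold changes). Genes with
    zero counts in both groups are excluded before testing, so the BH family
    size m is the number of genes actually tested; they are reported with
    ``tested = False``.
    """
    if regime not in DE_REGIMES:
        raise ValueError(f"unknown regime {regime!r}; choose from {list(DE_REGIMES)}")
    alpha, lfc_floor = DE_REGIMES[regime]
    if ds.norm is None:
        raise ValueError("dataset must be normalized before DE")

    groups = np.asarray(groups)
    uniq = np.unique(groups)
    if len(uniq) != 2:
        raise ValueError(f"groups must take exactly 2 values, got {uniq!r}")
    g1 = groups == uniq[1]
    g2 = groups == uniq[0]
    n1, n2 = int(g1.sum()), int(g2.sum())
    if min(n1, n2) < 3:
        import warnings

        warnings.warn(f"group sizes {n1}/{n2} < 3: DE results are low-powered",
                      stacklevel=2)

    norm = ds.norm.tocsr()
    counts = ds.counts.tocsr()
    records = []
    for gi, gene in enumerate(ds.genes):
        crow = np.asarray(counts[gi].todense()).ravel()
        if crow[g1].sum() == 0 and crow[g2].sum() == 0:
            records.append((gene, n1, n2, np.nan, np.nan, False, ""))
            continue
        row = np.asarray(norm[gi].todense()).ravel()
        res = wilcoxon_test(row[g1], row[g2])
        lfc = avg_log2fc(row[g1], row[g2], pseudo=pseudo)
        records.append((gene, n1, n2, lfc, res.p_value, True, res.method))

    out = pd.DataFrame(
        records,
        columns=["gene", "n1", "n2", "avg_log2fc", "p", "tested", "method"],
    )
    out["q"] = np.nan
    tested = out["tested"].to_numpy()
    if tested.any():
        out.loc[tested, "q"] = bh_adjust(out.loc[tested, "p"].to_numpy())
    out["significant"] = (
        tested & (out["q"] < alpha) & (out["avg_log2fc"].abs() >= lfc_floor)
    )
    out.attrs["regime"] = regime
    out.attrs["group1"], out.attrs["group2"] = str(uniq[1]), str(uniq[0])
    return out
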