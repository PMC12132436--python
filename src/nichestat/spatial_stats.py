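"""Spatial statistics: cross-type distances, KS comparison, neighborhood
density and density-effect regressions.

The neighborhood metric ``n`` of a cell is the number of other cells of the
same sample within a fixed radius (default 100 um, boundary inclusive).
Cells with ``n == 1`` sit in sparse areas, cells with ``n >= 5`` in dense
areas; everything else is "other" and excluded from sparse/dense contrasts.

Cross-type distance distributions collect all pairwise Euclidean distances
between cells of two types within each sample, then pool samples by
condition; pooled pairwise distances are not independent, so the KS p-value
is a descriptive comparison of the two ECDFs, not a calibrated test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from .dataset import SpatialDataset
from .diffexpr import bh_adjust

SPARSE, DENSE, OTHER = "sparse", "dense", "other"


@dataclass
class DistanceDistribution:
    """All cross-type pairwise distances for one condition (or sample)."""

    type_pair: tuple[str, str]
    condition: str
    distances: np.ndarray
    samples: list[str] = field(default_factory=list)

    @property
    def n_pairs(self) -> int:
        return len(self.distances)

    @property
    def empty(self) -> bool:
        return self.n_pairs == 0


@dataclass
class KSResult:
    D: float
    p_value: float
    n1: int
    n2: int


def cross_type_distances(
    ds: SpatialDataset,
    calls: pd.DataFrame,
    type_a: str,
    type_b: str,
    group_by_condition: bool = True,
) -> list[DistanceDistribution]:
    """Pairwise Euclidean distances between cells of two types.

    Distances are formed within each sample only (cells of different slices
    are never paired) and pooled per condition when ``group_by_condition``.
    A condition where either type is absent from every sample yields an
    empty, flagged distribution rather than an error.
    """
    if type_a == type_b:
        raise ValueError("type_a and type_b must differ for a cross-type distribution")
    if not calls["cell_id"].equals(ds.cell_ids):
        raise ValueError("calls are not aligned to the dataset")

    cells = ds.cells.assign(call=calls["call"].to_numpy())
    group_col = "condition" if group_by_condition else "sample_id"
    out = []
    for group, sub in cells.groupby(group_col, sort=True):
        chunks, samples = [], []
        for sample, ssub in sub.groupby("sample_id", sort=True):
            a = ssub.loc[ssub["call"] == type_a, ["x_um", "y_um"]].to_numpy(float)
            b = ssub.loc[ssub["call"] == type_b, ["x_um", "y_um"]].to_numpy(float)
            samples.append(str(sample))
            if len(a) and len(b):
                chunks.append(cdist(a, b).ravel())
        dist = np.concatenate(chunks) if chunks else np.array([])
        if dist.size == 0:
            warnings.warn(
                f"no {type_a}/{type_b} pairs in group {group!r}; empty distribution",
                stacklevel=2,
            )
        out.append(
            DistanceDistribution(
                type_pair=(type_a, type_b),
                condition=str(group),
                distances=np.sort(dist),
                samples=samples,
            )
        )
    return out


def ks_compare(d1: DistanceDistribution, d2: DistanceDistribution) -> KSResult:
    """Two-sample two-sided Kolmogorov-Smirnov comparison (asymptotic p)."""
    for side, d in (("first", d1), ("second", d2)):
        if d.empty:
            raise ValueError(f"{side} distribution ({d.condition}) is empty")
    res = stats.ks_2samp(d1.distances, d2.distances, method="asymp")
    return KSResult(
        D=float(res.statistic),
        p_value=float(res.pvalue),
        n1=d1.n_pairs,
        n2=d2.n_pairs,
    )


def neighborhood_counts(ds: SpatialDataset, radius_um: float = 100.0) -> pd.DataFrame:
    """Per-cell neighbor count ``n`` within ``radius_um`` (inclusive), per sample.

    Self is excluded; all cells count as neighbors regardless of type. Also
    emits ``dist_to_border``, the distance to the sample's coordinate
    bounding box, so users can filter cells subject to edge effects.
    """
    if radius_um <= 0:
        raise ValueError("radius_um must be positive")
    n = np.zeros(ds.n_cells, dtype=int)
    border = np.zeros(ds.n_cells, dtype=float)
    for _, idx in ds.cells.groupby("sample_id", sort=False).indices.items():
        pts = ds.cells.loc[idx, ["x_um", "y_um"]].to_numpy(float)
        tree = cKDTree(pts)
        n[idx] = tree.query_ball_point(pts, r=radius_um, return_length=True) - 1
        lo, hi = pts.min(axis=0), pts.max(axis=0)
        border[idx] = np.minimum(pts - lo, hi - pts).min(axis=1)
    return pd.DataFrame(
        {
            "cell_id": ds.cell_ids,
            "sample_id": ds.cells["sample_id"],
            "n": n,
            "dist_to_border": border,
        }
    )


def classify_density(
    profile: pd.DataFrame, sparse_n: int = 1, dense_min: int = 5
) -> pd.DataFrame:
    """Label each cell sparse (n == sparse_n), dense (n >= dense_min) or other."""
    if sparse_n >= dense_min:
        raise ValueError("sparse_n must be below dense_min")
    n = profile["n"].to_numpy()
    cls = np.where(n == sparse_n, SPARSE, np.where(n >= dense_min, DENSE, OTHER))
    return profile.assign(density_class=cls)


def _linear_arm(expr: np.ndarray, n_cov: np.ndarray) -> pd.DataFrame:
    """Vectorized per-gene simple OLS of expression on the neighbor count.

    Closed-form slope/SE/t with df = m - 2; equivalent to fitting each gene
    with an intercept term separately (cross-checked against statsmodels in
    the test suite).
    """
    m = len(n_cov)
    xc = n_cov - n_cov.mean()
    sxx = float(xc @ xc)
    yc = expr - expr.mean(axis=1, keepdims=True)
    slope = (yc @ xc) / sxx
    rss = (yc**2).sum(axis=1) - slope**2 * sxx
    rss = np.maximum(rss, 0.0)
    dof = m - 2
    sigma2 = rss / dof
    se = np.sqrt(sigma2 / sxx)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = slope / se
    p = 2.0 * stats.t.sf(np.abs(tstat), dof)
    zero_var = np.ptp(yc, axis=1) == 0
    p[zero_var] = np.nan
    tcrit = stats.t.ppf(0.975, dof)
    return pd.DataFrame(
        {
            "linear_slope": slope,
            "linear_se": se,
            "linear_p": p,
            "linear_ci_low": slope - tcrit * se,
            "linear_ci_high": slope + tcrit * se,
            "linear_flag": np.where(zero_var, "zero_variance", ""),
        }
    )


def _logistic_arm(expr: np.ndarray, dense01: np.ndarray) -> pd.DataFrame:
    """Per-gene logistic regression of density class (dense=1) on expression."""
    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import PerfectSeparationError

    coefs, ps, flags = [], [], []
    design_const = np.ones((len(dense01), 1))
    for row in expr:
        if np.ptp(row) == 0:
            coefs.append(np.nan)
            ps.append(np.nan)
            flags.append("zero_variance")
            continue
        X = np.column_stack([design_const, row])
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = sm.Logit(dense01, X).fit(disp=0, maxiter=100)
            if not np.isfinite(fit.bse[1]) or fit.bse[1] > 1e4:
                raise PerfectSeparationError("unstable standard error")
            coefs.append(float(fit.params[1]))
            ps.append(float(fit.pvalues[1]))
            flags.append("")
        except (PerfectSeparationError, np.linalg.LinAlgError, ValueError):
            coefs.append(np.nan)
            ps.append(np.nan)
            flags.append("separation_or_singular")
    return pd.DataFrame(
        {"logistic_coef": coefs, "logistic_p": ps, "logistic_flag": flags}
    )


def density_expression_test(
    ds: SpatialDataset,
    calls: pd.DataFrame,
    profile: pd.DataFrame,
    cell_type: str,
    genes: list[str] | None = None,
) -> pd.DataFrame:
    """Per-gene density-effect tests within one cell type.

    Linear arm: OLS of log-normalized expression on ``n`` over all cells of
    the type. Logistic arm: regression of density class (dense = 1,
    sparse = 0) on expression over sparse and dense cells only. BH adjustment
    is applied separately within each arm, across the genes tested.
    """
    if ds.norm is None:
        raise ValueError("dataset must be normalized before density testing")
    if "density_class" not in profile.columns:
        raise ValueError("profile lacks density_class; run classify_density first")
    if not calls["cell_id"].equals(ds.cell_ids):
        raise ValueError("calls are not aligned to the dataset")

    genes = genes if genes is not None else list(ds.genes)
    rows = [ds.gene_index(g) for g in genes]
    in_type = (calls["call"] == cell_type).to_numpy()
    if in_type.sum() < 3:
        raise ValueError(f"fewer than 3 cells of type {cell_type!r}")

    expr = np.asarray(ds.norm[rows][:, in_type].todense())
    n_cov = profile.loc[in_type, "n"].to_numpy(float)

    out = pd.DataFrame({"gene": genes, "cell_type": cell_type})
    if len(np.unique(n_cov)) < 2:
        out["linear_flag"] = "constant_covariate"
        for c in ("linear_slope", "linear_se", "linear_p", "linear_ci_low",
                  "linear_ci_high", "q_linear"):
            out[c] = np.nan
    else:
        out = pd.concat([out, _linear_arm(expr, n_cov)], axis=1)
        out["q_linear"] = _bh_with_nan(out["linear_p"].to_numpy())

    cls = profile.loc[in_type, "density_class"].to_numpy()
    sd_mask = np.isin(cls, [SPARSE, DENSE])
    dense01 = (cls[sd_mask] == DENSE).astype(float)
    if sd_mask.sum() < 6 or len(np.unique(dense01)) < 2:
        out["logistic_flag"] = "insufficient_sparse_dense_cells"
        for c in ("logistic_coef", "logistic_p", "q_logistic"):
            out[c] = np.nan
    else:
        out = pd.concat([out, _logistic_arm(expr[:, sd_mask], dense01)], axis=1)
        out["q_logistic"] = _bh_with_nan(out["logistic_p"].to_numpy())
    return out


def _bh_with_nan(p: np.ndarray) -> np.ndarray:
    """BH over the finite entries; NaN rows stay NaN."""
    q = np.full(len(p), np.nan)
    ok = np.isfinite(p)
    if ok.any():
        q[ok] = bh_adjust(p[ok])
    return q
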