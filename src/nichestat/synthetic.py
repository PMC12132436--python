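"""Synthetic spatial transcriptomics generator with planted ground truth.

Emulates a targeted-panel run on organoid slices: per sample, cell positions
follow a homogeneous Poisson background superposed on a Thomas cluster
process (Poisson parents, Poisson-distributed offspring displaced by an
isotropic Gaussian), giving rosette-like aggregates. Each cell draws a type
from its condition's proportions; counts are negative binomial with a mean
that encodes exclusive markers, condition fold-changes and local-density
effects, then thinned by independent dropout. Every planted parameter is
returned as ground truth so recovery tests can close the loop.

The Thomas process is used because its intensity has a closed form,
``background + parent_intensity * mean_offspring``, which moment checks can
verify directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import sparse
from scipy.spatial import cKDTree

from .cell_typing import DEFAULT_PANEL_GENES, UNDEFINED
from .dataset import SpatialDataset
from .io_qc import write_dataset

CONDITIONS = ("control", "mct8")
MAX_EXPECTED_CELLS = 50_000

_DEFAULT_PROPORTIONS = {"npc": 0.4, "ipc": 0.2, "neuron": 0.3, UNDEFINED: 0.1}


def _default_de_genes() -> list[tuple[str, float]]:
    # balanced up/down regulation, as in real condition contrasts
    up = [(f"G{i:04d}", 1.0) for i in range(1, 11)]
    down = [(f"G{i:04d}", -1.0) for i in range(11, 21)]
    return up + down


def _default_density_genes() -> list[tuple[str, float]]:
    return [(f"G{i:04d}", 0.03) for i in range(21, 26)]


@dataclass
class SimConfig:
    """Parameters of one simulated study (two conditions, several slices).

    Intensities are cells per square micrometre; the default geometry
    (3 mm x 3 mm field, background 4e-5, ~40 cluster parents of ~28
    offspring each with 40 um spread) yields roughly 1,500 cells per
    control sample, with the disease condition thinned to 75% density.
    """

    seed: int = 0
    n_samples_per_condition: int = 2
    field_size_um: tuple[float, float] = (3000.0, 3000.0)
    background_intensity: float = 4e-5
    cluster_parent_intensity: float = 4.5e-6
    cluster_mean_offspring: float = 28.0
    cluster_sigma_um: float = 40.0
    condition_density_scale: dict[str, float] = dc_field(
        default_factory=lambda: {"control": 1.0, "mct8": 0.75}
    )
    type_proportions: dict[str, dict[str, float]] = dc_field(
        default_factory=lambda: {c: dict(_DEFAULT_PROPORTIONS) for c in CONDITIONS}
    )
    composition_shift: dict[str, float] | None = None
    n_genes: int = 1207
    marker_fold: float = 8.0
    nb_mean_baseline: float = 0.5
    nb_dispersion: float = 5.0
    dropout_rate: float = 0.02
    density_genes: list[tuple[str, float]] = dc_field(
        default_factory=_default_density_genes
    )
    de_genes: list[tuple[str, float]] = dc_field(default_factory=_default_de_genes)
    radius_um: float = 100.0

    def __post_init__(self) -> None:
        for cond, props in self.type_proportions.items():
            s = sum(props.values())
            if not np.isclose(s, 1.0):
                raise ValueError(f"type proportions for {cond!r} sum to {s}, not 1")
        for name in ("background_intensity", "cluster_parent_intensity",
                     "cluster_mean_offspring", "cluster_sigma_um"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0 <= self.dropout_rate <= 1:
            raise ValueError("dropout_rate must lie in [0, 1]")

    # -- derived quantities ---------------------------------------------

    @property
    def area_um2(self) -> float:
        return self.field_size_um[0] * self.field_size_um[1]

    def expected_cells_per_sample(self, condition: str) -> float:
        scale = self.condition_density_scale.get(condition, 1.0)
        lam = self.background_intensity + (
            self.cluster_parent_intensity * self.cluster_mean_offspring
        )
        return self.area_um2 * lam * scale

    def gene_names(self) -> list[str]:
        markers = [g for gs in DEFAULT_PANEL_GENES.values() for g in gs]
        n_other = self.n_genes - len(markers)
        if n_other < 0:
            raise ValueError(f"n_genes must be >= {len(markers)} (the marker panel)")
        return markers + [f"G{i:04d}" for i in range(1, n_other + 1)]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "field_size_um" in raw:
            raw["field_size_um"] = tuple(raw["field_size_um"])
        for key in ("density_genes", "de_genes"):
            if key in raw:
                raw[key] = [(str(g), float(v)) for g, v in raw[key]]
        return cls(**raw)


def small_config(seed: int = 0) -> SimConfig:
    """Desk-scale preset: ~150 cells per sample, 120-gene panel."""
    return SimConfig(
        seed=seed,
        field_size_um=(1500.0, 1500.0),
        background_intensity=2e-5,
        cluster_parent_intensity=2.2e-6,
        cluster_mean_offspring=22.0,
        n_genes=120,
    )


@dataclass
class GroundTruth:
    """Planted parameters recorded at generation time."""

    cell_truth: pd.DataFrame  # cell_id, sample_id, condition, true_type, n_true
    gene_truth: pd.DataFrame  # gene, role, param
    total_counts: int


def _sample_points(cfg: SimConfig, rng: np.random.Generator, scale: float) -> np.ndarray:
    w, h = cfg.field_size_um
    n_bg = rng.poisson(cfg.background_intensity * scale * cfg.area_um2)
    pts = [rng.uniform([0, 0], [w, h], size=(n_bg, 2))]
    n_parents = rng.poisson(cfg.cluster_parent_intensity * scale * cfg.area_um2)
    parents = rng.uniform([0, 0], [w, h], size=(n_parents, 2))
    for p in parents:
        k = rng.poisson(cfg.cluster_mean_offspring)
        off = p + rng.normal(scale=cfg.cluster_sigma_um, size=(k, 2))
        inside = (
            (off[:, 0] >= 0) & (off[:, 0] <= w) & (off[:, 1] >= 0) & (off[:, 1] <= h)
        )
        pts.append(off[inside])
    return np.vstack(pts)


def _condition_proportions(cfg: SimConfig, condition: str) -> dict[str, float]:
    props = dict(cfg.type_proportions[condition])
    if cfg.composition_shift and condition == CONDITIONS[1]:
        for t, mult in cfg.composition_shift.items():
            props[t] = props[t] * mult
        total = sum(props.values())
        props = {t: v / total for t, v in props.items()}
    return props


def simulate(cfg: SimConfig) -> tuple[SpatialDataset, GroundTruth]:
    """Draw one full study; deterministic given ``cfg`` (incl. its seed)."""
    expected = sum(
        cfg.expected_cells_per_sample(c) * cfg.n_samples_per_condition
        for c in CONDITIONS
    )
    if expected > MAX_EXPECTED_CELLS:
        raise ValueError(
            f"expected ~{expected:.0f} cells exceeds the {MAX_EXPECTED_CELLS} cap; "
            "reduce intensities, field size or sample count"
        )

    genes = cfg.gene_names()
    gene_idx = {g: i for i, g in enumerate(genes)}
    type_names = list(DEFAULT_PANEL_GENES) + [UNDEFINED]
    marker_rows = {
        t: np.array([gene_idx[g] for g in gs]) for t, gs in DEFAULT_PANEL_GENES.items()
    }
    for g, _ in cfg.de_genes + cfg.density_genes:
        if g not in gene_idx:
            raise ValueError(f"planted gene {g!r} is not in the simulated panel")

    meta_frames, count_blocks, truth_frames = [], [], []
    for ci, cond in enumerate(CONDITIONS):
        props = _condition_proportions(cfg, cond)
        p_vec = np.array([props.get(t, 0.0) for t in type_names])
        scale = cfg.condition_density_scale.get(cond, 1.0)
        for si in range(cfg.n_samples_per_condition):
            rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, ci, si]))
            pts = _sample_points(cfg, rng, scale)
            n_cells = len(pts)
            sample_id = f"{cond}_s{si + 1}"
            cell_ids = [f"{sample_id}_c{i:05d}" for i in range(n_cells)]
            types = np.array(type_names, dtype=object)[
                rng.choice(len(type_names), size=n_cells, p=p_vec)
            ]
            if n_cells:
                tree = cKDTree(pts)
                n_true = tree.query_ball_point(
                    pts, r=cfg.radius_um, return_length=True
                ) - 1
            else:
                n_true = np.zeros(0, dtype=int)

            mean = np.full((len(genes), n_cells), cfg.nb_mean_baseline)
            for t, rows in marker_rows.items():
                mean[np.ix_(rows, np.arange(n_cells))] = 0.0
                own = types == t
                mean[np.ix_(rows, np.flatnonzero(own))] = (
                    cfg.nb_mean_baseline * cfg.marker_fold
                )
            if ci == 1:
                for g, lfc in cfg.de_genes:
                    mean[gene_idx[g]] *= 2.0**lfc
            for g, beta in cfg.density_genes:
                mean[gene_idx[g]] *= np.exp(np.minimum(beta * n_true, 50.0))

            theta = cfg.nb_dispersion
            p_nb = theta / (theta + mean)
            counts = rng.negative_binomial(theta, p_nb)
            if cfg.dropout_rate > 0:
                keep = rng.random(counts.shape) >= cfg.dropout_rate
                counts = counts * keep

            meta_frames.append(
                pd.DataFrame(
                    {
                        "cell_id": cell_ids,
                        "x_um": pts[:, 0],
                        "y_um": pts[:, 1],
                        "sample_id": sample_id,
                        "condition": cond,
                    }
                )
            )
            count_blocks.append(sparse.csc_matrix(counts))
            truth_frames.append(
                pd.DataFrame(
                    {
                        "cell_id": cell_ids,
                        "sample_id": sample_id,
                        "condition": cond,
                        "true_type": types,
                        "n_true": n_true,
                    }
                )
            )

    cells = pd.concat(meta_frames, ignore_index=True)
    counts = sparse.hstack(count_blocks, format="csc")
    ds = SpatialDataset(cells=cells, genes=genes, counts=counts)

    roles, params = [], []
    de_map = dict(cfg.de_genes)
    dens_map = dict(cfg.density_genes)
    marker_of = {g: t for t, gs in DEFAULT_PANEL_GENES.items() for g in gs}
    for g in genes:
        if g in marker_of:
            roles.append(f"marker:{marker_of[g]}")
            params.append(cfg.marker_fold)
        elif g in de_map:
            roles.append("de")
            params.append(de_map[g])
        elif g in dens_map:
            roles.append("density")
            params.append(dens_map[g])
        else:
            roles.append("null")
            params.append(0.0)
    gt = GroundTruth(
        cell_truth=pd.concat(truth_frames, ignore_index=True),
        gene_truth=pd.DataFrame({"gene": genes, "role": roles, "param": params}),
        total_counts=int(ds.counts.sum()),
    )
    return ds, gt


def write_fixture(ds: SpatialDataset, gt: GroundTruth, out_dir: str | Path) -> dict:
    """Write the dataset flat files plus a combined ground-truth TSV.

    The ground-truth file has one row per cell followed by one row per gene
    (``kind`` column distinguishes them), so its row count is
    ``n_cells + n_genes``.
    """
    out_dir = Path(out_dir)
    paths = write_dataset(ds, out_dir)
    cell_part = gt.cell_truth.assign(kind="cell").rename(columns={"cell_id": "id"})
    gene_part = gt.gene_truth.assign(kind="gene").rename(columns={"gene": "id"})
    combined = pd.concat([cell_part, gene_part], ignore_index=True)
    cols = ["kind", "id", "sample_id", "condition", "true_type", "n_true",
            "role", "param"]
    combined = combined.reindex(columns=cols)
    gt_path = out_dir / "ground_truth.tsv"
    combined.to_csv(gt_path, sep="\t", index=False)
    paths["ground_truth"] = gt_path
    return paths
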