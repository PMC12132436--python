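"""End-to-end orchestration: simulate/load -> QC -> normalize -> annotate
-> spatial statistics -> differential expression -> composition.

Outputs are a flat directory of TSVs plus a machine-readable ``report.json``
naming every file each stage produced, with per-stage row counts and a
reproducible hash of the configuration. Any stage failure aborts with the
stage name.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .cell_typing import MarkerPanel, assign_types
from .composition import composition_table, pairwise_proportions
from .dataset import SpatialDataset
from .diffexpr import run_de
from .io_qc import normalize, qc_filter, read_dataset
from .spatial_stats import (
    classify_density,
    cross_type_distances,
    density_expression_test,
    ks_compare,
    neighborhood_counts,
)
from .synthetic import SimConfig, simulate, write_fixture

logger = logging.getLogger("nichestat")


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage {stage!r}: {message}")


@dataclass
class RunConfig:
    """One pipeline run: either a simulation block or input file paths."""

    out_dir: str
    simulation: SimConfig | None = None
    inputs: dict[str, str] | None = None  # metadata, matrix, optional genes/cells
    qc_min_probes: int = 15
    qc_min_transcripts: int = 20
    normalize_scale: float = 1e4
    panel: MarkerPanel = field(default_factory=MarkerPanel)
    radius_um: float = 100.0
    sparse_n: int = 1
    dense_min: int = 5
    distance_pairs: list[tuple[str, str]] = field(
        default_factory=lambda: [("npc", "neuron")]
    )
    de_regime: str = "cosmx"
    seed: int | None = None

    def __post_init__(self) -> None:
        if (self.simulation is None) == (self.inputs is None):
            raise ValueError("exactly one of simulation/inputs must be given")
        if self.seed is not None and self.simulation is not None:
            self.simulation.seed = self.seed

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "simulation" in raw and raw["simulation"] is not None:
            sim = raw["simulation"]
            if "field_size_um" in sim:
                sim["field_size_um"] = tuple(sim["field_size_um"])
            raw["simulation"] = SimConfig(**sim)
        if "panel" in raw and raw["panel"] is not None:
            p = raw["panel"]
            raw["panel"] = (
                MarkerPanel.from_yaml(p) if isinstance(p, str) else MarkerPanel(types=p)
            )
        if "distance_pairs" in raw:
            raw["distance_pairs"] = [tuple(pair) for pair in raw["distance_pairs"]]
        return cls(**raw)

    def config_hash(self) -> str:
        def enc(obj):
            if isinstance(obj, SimConfig):
                return asdict(obj)
            if isinstance(obj, MarkerPanel):
                return obj.types
            return obj

        # out_dir is where results land, not what they are — keep it out of
        # the hash so identical analyses hash identically
        payload = {k: enc(v) for k, v in vars(self).items() if k != "out_dir"}
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()


@dataclass
class RunReport:
    version: str
    config_hash: str
    stage_rows: dict[str, int]
    manifest: dict[str, list[str]]
    warnings: list[str]

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(vars(self), fh, indent=2)


def run(config: RunConfig) -> RunReport:
    """Execute all stages in fixed order; returns the run report."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, list[str]] = {}
    stage_rows: dict[str, int] = {}
    caught: list[str] = []

    def record(stage: str, files: list[Path], rows: int) -> None:
        manifest[stage] = [str(f.relative_to(out)) for f in files]
        stage_rows[stage] = rows
        logger.info("stage %-11s rows=%-7d files=%s", stage, rows, manifest[stage])

    t0 = time.time()
    with warnings.catch_warnings(record=True) as wlist:
        warnings.simplefilter("always")

        # -- input -------------------------------------------------------
        try:
            if config.simulation is not None:
                ds, gt = simulate(config.simulation)
                paths = write_fixture(ds, gt, out / "input")
            else:
                ds = read_dataset(**config.inputs)
                paths = {"metadata": Path(config.inputs["metadata"])}
        except Exception as exc:
            raise StageError("input", str(exc)) from exc
        record("input", [p for p in paths.values() if str(p).startswith(str(out))]
               or list(paths.values())[:1], ds.n_cells)

        # -- qc ----------------------------------------------------------
        try:
            ds_qc, qc_report = qc_filter(
                ds, config.qc_min_probes, config.qc_min_transcripts
            )
            qc_path = out / "qc_report.tsv"
            qc_report.to_tsv(qc_path)
        except Exception as exc:
            raise StageError("qc", str(exc)) from exc
        record("qc", [qc_path], ds_qc.n_cells)

        # -- normalize ---------------------------------------------------
        try:
            if ds_qc.n_cells > 0:
                ds_norm = normalize(ds_qc, config.normalize_scale)
            else:
                ds_norm = ds_qc
            norm_path = out / "cell_totals.tsv"
            pd.DataFrame(
                {"cell_id": ds_norm.cell_ids, "total_counts": ds_norm.total_counts()}
            ).to_csv(norm_path, sep="\t", index=False)
        except Exception as exc:
            raise StageError("normalize", str(exc)) from exc
        record("normalize", [norm_path], ds_norm.n_cells)

        # -- annotate ----------------------------------------------------
        if ds_norm.n_cells == 0:
            raise StageError(
                "annotate", "empty dataset after qc stage removed every cell"
            )
        try:
            calls = assign_types(ds_norm, config.panel)
            calls_path = out / "cell_types.tsv"
            calls.to_csv(calls_path, sep="\t", index=False)
        except Exception as exc:
            raise StageError("annotate", str(exc)) from exc
        record("annotate", [calls_path], len(calls))

        # -- spatial -----------------------------------------------------
        try:
            profile = classify_density(
                neighborhood_counts(ds_norm, config.radius_um),
                config.sparse_n,
                config.dense_min,
            )
            prof_path = out / "neighborhood.tsv"
            profile.to_csv(prof_path, sep="\t", index=False)

            dist_rows, ks_rows = [], []
            for ta, tb in config.distance_pairs:
                dists = cross_type_distances(ds_norm, calls, ta, tb)
                for d in dists:
                    for val in d.distances:
                        dist_rows.append((f"{ta}-{tb}", d.condition, val))
                nonempty = [d for d in dists if not d.empty]
                if len(nonempty) == 2:
                    ks = ks_compare(*nonempty)
                    ks_rows.append(
                        (f"{ta}-{tb}", nonempty[0].condition, nonempty[1].condition,
                         ks.D, ks.p_value, ks.n1, ks.n2)
                    )
            dist_path = out / "distances.tsv"
            pd.DataFrame(
                dist_rows, columns=["type_pair", "condition", "distance_um"]
            ).to_csv(dist_path, sep="\t", index=False)
            ks_path = out / "ks_tests.tsv"
            pd.DataFrame(
                ks_rows,
                columns=["type_pair", "cond1", "cond2", "D", "p_value", "n1", "n2"],
            ).to_csv(ks_path, sep="\t", index=False)

            dens_frames = []
            for t in config.panel.type_names:
                try:
                    dens_frames.append(
                        density_expression_test(ds_norm, calls, profile, t)
                    )
                except ValueError as exc:
                    caught.append(f"density test skipped for {t}: {exc}")
            dens_path = out / "density_tests.tsv"
            (
                pd.concat(dens_frames, ignore_index=True)
                if dens_frames
                else pd.DataFrame()
            ).to_csv(dens_path, sep="\t", index=False)
        except StageError:
            raise
        except Exception as exc:
            raise StageError("spatial", str(exc)) from exc
        record("spatial", [prof_path, dist_path, ks_path, dens_path], len(profile))

        # -- de ----------------------------------------------------------
        try:
            de = run_de(ds_norm, ds_norm.cells["condition"], regime=config.de_regime)
            de_path = out / "de_results.tsv"
            de.to_csv(de_path, sep="\t", index=False)
        except Exception as exc:
            raise StageError("de", str(exc)) from exc
        record("de", [de_path], len(de))

        # -- composition -------------------------------------------------
        try:
            table = composition_table(calls, ds_norm)
            comp = pairwise_proportions(table)
            comp_path = out / "composition.tsv"
            per = comp.per_cluster.copy()
            per.insert(0, "scope", "per_cluster")
            globrow = pd.DataFrame(
                [{"scope": "global", "chi2": comp.global_test.chi2,
                  "p": comp.global_test.p_value, "cluster": "(all)"}]
            )
            pd.concat([globrow, per], ignore_index=True).to_csv(
                comp_path, sep="\t", index=False
            )
        except Exception as exc:
            raise StageError("composition", str(exc)) from exc
        record("composition", [comp_path], len(comp.per_cluster))

        caught.extend(str(w.message) for w in wlist)

    logger.info("pipeline finished in %.1f s", time.time() - t0)
    report = RunReport(
        version=__version__,
        config_hash=config.config_hash(),
        stage_rows=stage_rows,
        manifest=manifest,
        warnings=caught,
    )
    report.to_json(out / "report.json")
    return report
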