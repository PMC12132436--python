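"""Rule-based cell-type annotation from exclusive marker panels.

A cell is assigned to a type when it expresses at least one of that type's
marker genes and none of any other type's markers; everything else —
including cells hitting markers of two types — is "undefined". This mirrors
the presence/absence logic used for targeted-panel organoid data, where the
cortical populations of interest (neural precursors, intermediate
precursors, neurons) carry mutually exclusive marker sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .dataset import SpatialDataset

UNDEFINED = "undefined"

#: Default cortical-organoid panel: NPC / IPC / projection-neuron markers.
DEFAULT_PANEL_GENES: dict[str, list[str]] = {
    "npc": ["VIM", "NOTCH1", "BMP7"],
    "ipc": ["EOMES", "BMP5"],
    "neuron": ["GATA3", "DCN", "SPOCK2", "SOX4"],
}


class PanelError(ValueError):
    """Raised for malformed marker panels."""


@dataclass
class MarkerPanel:
    """Mapping of cell-type name to its exclusive marker genes."""

    types: dict[str, list[str]] = field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_PANEL_GENES.items()}
    )

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for t, markers in self.types.items():
            if not markers:
                raise PanelError(f"cell type {t!r} has no markers")
            for g in markers:
                if g in seen:
                    raise PanelError(
                        f"marker {g!r} listed under both {seen[g]!r} and {t!r}"
                    )
                seen[g] = t
        if UNDEFINED in self.types:
            raise PanelError(f"{UNDEFINED!r} is reserved for unassigned cells")

    @property
    def type_names(self) -> list[str]:
        return list(self.types)

    @property
    def all_markers(self) -> list[str]:
        return [g for markers in self.types.values() for g in markers]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "MarkerPanel":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(types={str(t): [str(g) for g in gs] for t, gs in raw.items()})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.types, fh, sort_keys=False)


def assign_types(
    ds: SpatialDataset, panel: MarkerPanel | None = None, min_count: int = 1
) -> pd.DataFrame:
    """Assign each cell a type by the exclusive-marker rule.

    "Expressed" means raw count >= ``min_count``. Returns a frame aligned to
    ``ds.cells`` with columns ``cell_id``, ``call`` and one ``hits_<type>``
    column per panel type giving the number of that type's markers detected.
    """
    panel = panel or MarkerPanel()
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    missing = [g for g in panel.all_markers if g not in ds.genes]
    if missing:
        raise PanelError(f"panel genes absent from dataset: {missing}")

    hits = {}
    for t, markers in panel.types.items():
        rows = [ds.gene_index(g) for g in markers]
        sub = ds.counts[rows, :]
        hits[t] = np.asarray((sub >= min_count).sum(axis=0)).ravel().astype(int)

    hit_mat = np.column_stack([hits[t] for t in panel.type_names])
    n_types_hit = (hit_mat > 0).sum(axis=1)
    calls = np.full(ds.n_cells, UNDEFINED, dtype=object)
    exclusive = n_types_hit == 1
    winner = np.argmax(hit_mat > 0, axis=1)
    names = np.array(panel.type_names, dtype=object)
    calls[exclusive] = names[winner[exclusive]]

    out = pd.DataFrame({"cell_id": ds.cell_ids, "call": calls})
    for t in panel.type_names:
        out[f"hits_{t}"] = hits[t]
    return out


def type_counts(calls: pd.DataFrame, ds: SpatialDataset) -> pd.DataFrame:
    """Condition x cell-type count table (rows sum to cells per condition)."""
    if len(calls) != ds.n_cells or not calls["cell_id"].equals(ds.cell_ids):
        raise ValueError("calls are not aligned to the dataset")
    if ds.n_cells == 0:
        return pd.DataFrame()
    df = pd.DataFrame({"condition": ds.cells["condition"], "call": calls["call"]})
    return df.groupby(["condition", "call"], observed=True).size().unstack(fill_value=0)
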