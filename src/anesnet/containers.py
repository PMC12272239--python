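"""Core in-memory containers shared across the pipeline.

The substrate of the state classifier is the *carpet matrix*: a voxel x time
array of BOLD signal spanning one or more concatenated runs, with per-voxel
region/hemisphere tags and per-run boundaries.  Graph analyses operate on a
node x node Pearson adjacency matrix annotated by a parcellation table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CarpetMatrix",
    "Parcellation",
    "check_adjacency",
]


@dataclass
class CarpetMatrix:
    """Voxel (or node) x time BOLD signal array with run structure.

    Parameters
    ----------
    data : ndarray of shape (n_voxels, n_time)
        BOLD signal, one row per voxel/node.
    run_boundaries : list of (start, end)
        Half-open volume index ranges partitioning the time axis.  A single
        run spanning all volumes is assumed when omitted.
    tr_seconds : float
        Repetition time in seconds (sampling interval of the time axis).
    voxel_labels : DataFrame, optional
        One row per voxel with at least ``region`` and ``hemisphere`` columns.
    condition : str
        Free-text acquisition label (e.g. an anesthesia concentration).
    """

    data: np.ndarray
    tr_seconds: float = 2.0
    run_boundaries: list[tuple[int, int]] | None = None
    voxel_labels: pd.DataFrame | None = None
    condition: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("carpet data must be 2-D (voxels x time)")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if self.run_boundaries is None:
            self.run_boundaries = [(0, self.data.shape[1])]
        self._check_boundaries()
        if self.voxel_labels is not None and len(self.voxel_labels) != self.data.shape[0]:
            raise ValueError("voxel_labels length must match number of voxels")

    def _check_boundaries(self) -> None:
        bounds = sorted(self.run_boundaries)
        cursor = 0
        for start, end in bounds:
            if start != cursor or end <= start:
                raise ValueError(
                    f"run boundaries {self.run_boundaries} do not partition "
                    f"the time axis of length {self.data.shape[1]}"
                )
            cursor = end
        if cursor != self.data.shape[1]:
            raise ValueError("run boundaries do not cover the full time axis")

    @property
    def n_voxels(self) -> int:
        return self.data.shape[0]

    @property
    def n_time(self) -> int:
        return self.data.shape[1]

    @property
    def n_runs(self) -> int:
        return len(self.run_boundaries)

    def run_slices(self) -> list[slice]:
        return [slice(start, end) for start, end in self.run_boundaries]


@dataclass
class Parcellation:
    """Node table: id, name, hemisphere, homotopic partner, centroid, class.

    ``table`` columns: ``id`` (int), ``name`` (str), ``hemisphere`` ('L'/'R'),
    ``partner`` (id of the mirror node in the other hemisphere), ``x``, ``y``,
    ``z`` (centroid, mm), ``class`` ('cortical'/'subcortical').
    """

    table: pd.DataFrame
    required_columns = ("id", "name", "hemisphere", "partner", "x", "y", "z", "class")

    def __post_init__(self) -> None:
        missing = [c for c in self.required_columns if c not in self.table.columns]
        if missing:
            raise ValueError(f"parcellation table missing columns: {missing}")
        tab = self.table.set_index("id", drop=False)
        left = tab[tab["hemisphere"] == "L"]
        right = tab[tab["hemisphere"] == "R"]
        if len(left) != len(right):
            raise ValueError("hemispheres must have equal node counts")
        # homotopic pairing must be an involutive bijection L <-> R
        for _, row in tab.iterrows():
            partner = tab.loc[row["partner"]]
            if partner["hemisphere"] == row["hemisphere"]:
                raise ValueError("homotopic partner must lie in the opposite hemisphere")
            if partner["partner"] != row["id"]:
                raise ValueError("homotopic pairing is not symmetric")
        self._indexed = tab

    @property
    def n_nodes(self) -> int:
        return len(self.table)

    @property
    def node_ids(self) -> np.ndarray:
        return self.table["id"].to_numpy()

    def centroids(self) -> np.ndarray:
        return self.table[["x", "y", "z"]].to_numpy(dtype=float)

    def hemisphere_mask(self, hemisphere: str) -> np.ndarray:
        return (self.table["hemisphere"] == hemisphere).to_numpy()

    def partner_positions(self) -> np.ndarray:
        """Positional index of each node's homotopic partner."""
        pos = {nid: i for i, nid in enumerate(self.table["id"])}
        return np.array([pos[p] for p in self.table["partner"]], dtype=int)


def check_adjacency(a: np.ndarray, *, name: str = "adjacency") -> np.ndarray:
    """Validate a square symmetric correlation-like matrix and return it as float."""
    a = np.asarray(a, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError(f"{name} must be square, got shape {a.shape}")
    if not np.allclose(a, a.T, atol=1e-10, equal_nan=True):
        raise ValueError(f"{name} must be symmetric")
    return a
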