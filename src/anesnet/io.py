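"""Readers and writers for the pipeline's on-disk formats.

Formats: NIfTI-1 (4-D BOLD and 3-D maps/masks, via nibabel), node x time and
square adjacency matrices as TSV (tab-separated, UTF-8, header row of node
ids, floats at 9 significant digits), BIDS-style events TSV (onset, duration,
trial_type), parcellation TSV (id, name, hemisphere, partner, x, y, z,
class), and JSON run manifests / ground-truth records.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .containers import CarpetMatrix, Parcellation

__all__ = [
    "RunManifest",
    "read_bold",
    "write_matrix_tsv",
    "read_matrix_tsv",
    "write_events_tsv",
    "read_events_tsv",
    "write_parcellation_tsv",
    "read_parcellation_tsv",
    "write_bold_nifti",
    "read_manifest",
    "load_manifest_carpet",
]

FLOAT_FORMAT = "%.9g"


@dataclass
class RunManifest:
    """One entry per run: path, TR, condition, subject, optional events path."""

    run_id: str
    path: str
    tr_seconds: float
    condition: str = ""
    subject: str = ""
    events_path: str | None = None


def write_matrix_tsv(path: str | Path, data: np.ndarray, ids=None) -> None:
    """Write a 2-D array as TSV with a header row of row ids."""
    data = np.asarray(data)
    ids = ids if ids is not None else [f"n{i}" for i in range(data.shape[0])]
    df = pd.DataFrame(data.T, columns=[str(i) for i in ids])
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_matrix_tsv(path: str | Path) -> tuple[np.ndarray, list[str]]:
    """Read a TSV matrix; returns (rows x columns array, row ids)."""
    df = pd.read_csv(path, sep="\t")
    return df.to_numpy(dtype=float).T, list(df.columns)


def write_events_tsv(path: str | Path, events: pd.DataFrame) -> None:
    cols = [c for c in ("onset", "duration", "trial_type") if c in events.columns]
    events[cols].to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_events_tsv(path: str | Path) -> pd.DataFrame:
    events = pd.read_csv(path, sep="\t")
    if not {"onset", "duration"}.issubset(events.columns):
        raise ValueError(f"{path}: events TSV needs 'onset' and 'duration' columns")
    return events


def write_parcellation_tsv(path: str | Path, parcellation: Parcellation) -> None:
    parcellation.table.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_parcellation_tsv(path: str | Path) -> Parcellation:
    return Parcellation(pd.read_csv(path, sep="\t"))


def write_bold_nifti(path: str | Path, data4d: np.ndarray, tr_seconds: float,
                     affine: np.ndarray | None = None) -> None:
    """Write a 4-D array as NIfTI-1 with the TR recorded in the header."""
    affine = affine if affine is not None else np.eye(4)
    img = nib.Nifti1Image(np.asarray(data4d, dtype=np.float32), affine)
    img.header.set_zooms((*img.header.get_zooms()[:3], float(tr_seconds)))
    img.header.set_xyzt_units("mm", "sec")
    nib.save(img, str(path))


def read_bold(path: str | Path, tr_seconds: float | None = None,
              mask_path: str | Path | None = None) -> CarpetMatrix:
    """Load BOLD data as a (space, time) carpet matrix.

    ``.tsv`` files are node x time tables (header row of node ids).  NIfTI
    files are flattened over voxels, optionally restricted to a nonzero mask
    on the same grid; scaling slopes are applied by nibabel and the TR is
    taken from the header when not supplied.  NaN voxels are dropped with a
    warning.
    """
    path = Path(path)
    if path.suffix == ".tsv":
        data, _ = read_matrix_tsv(path)
        if tr_seconds is None:
            raise ValueError("TSV input carries no TR; pass tr_seconds")
        return CarpetMatrix(data, tr_seconds=tr_seconds)
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(dtype=np.float64))
    if data.ndim != 4:
        raise ValueError(f"{path}: expected 4-D BOLD, got shape {data.shape}")
    if tr_seconds is None:
        zooms = img.header.get_zooms()
        tr_seconds = float(zooms[3]) if len(zooms) > 3 else 0.0
        if tr_seconds <= 0:
            raise ValueError(f"{path}: TR missing from header; pass tr_seconds")
    flat = data.reshape(-1, data.shape[3])
    if mask_path is not None:
        mask_img = nib.load(str(mask_path))
        mask = np.asarray(mask_img.get_fdata()) > 0
        if mask.shape != data.shape[:3]:
            raise ValueError("mask grid does not match the BOLD grid")
        flat = flat[mask.reshape(-1)]
    bad = np.isnan(flat).any(axis=1)
    if bad.any():
        warnings.warn(f"{int(bad.sum())} NaN voxel(s) masked out")
        flat = flat[~bad]
    return CarpetMatrix(flat, tr_seconds=tr_seconds)


def read_manifest(path: str | Path) -> list[RunManifest]:
    """Read a JSON run manifest (list of run records)."""
    with open(path) as fh:
        entries = json.load(fh)
    runs = [RunManifest(**e) for e in entries]
    trs = {r.tr_seconds for r in runs}
    if len(trs) > 1:
        raise ValueError(f"inconsistent TRs in manifest: {sorted(trs)}")
    base = Path(path).parent
    for r in runs:
        if not (base / r.path).exists() and not Path(r.path).exists():
            raise FileNotFoundError(f"manifest run {r.run_id}: {r.path} not found")
    return runs


def load_manifest_carpet(path: str | Path) -> tuple[CarpetMatrix, list[str]]:
    """Concatenate all manifest runs into one carpet with run boundaries.

    Returns the carpet and the per-run condition labels.
    """
    runs = read_manifest(path)
    base = Path(path).parent
    blocks, boundaries, conditions = [], [], []
    cursor = 0
    for r in runs:
        p = base / r.path if (base / r.path).exists() else Path(r.path)
        carpet = read_bold(p, tr_seconds=r.tr_seconds)
        blocks.append(carpet.data)
        boundaries.append((cursor, cursor + carpet.n_time))
        cursor += carpet.n_time
        conditions.append(r.condition)
    data = np.concatenate(blocks, axis=1)
    return (
        CarpetMatrix(data, tr_seconds=runs[0].tr_seconds, run_boundaries=boundaries),
        conditions,
    )
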