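"""Core data types and delimited-text I/O for ramanome datasets.

A *ramanome* is the collection of single-cell Raman spectra (SCRS) acquired
from a cell population, all expressed on a shared wavenumber axis.  Two text
layouts are supported:

* **wide** — first column is the wavenumber (cm^-1), one column per cell.
  Optional metadata rows whose first-column value starts with ``_meta:`` may
  precede the numeric block (``_meta:batch_id`` etc.).
* **long** — columns ``cell_id, wavenumber, intensity`` plus optional
  metadata columns (``sample_id``, ``batch_id``, ``label``, ``d2o_hours``).

All operations are pure: they return new objects and never mutate inputs.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CALIBRATION_RANGE",
    "WavenumberAxis",
    "SingleCellSpectrum",
    "Ramanome",
    "read_spectra",
    "write_spectra",
    "harmonize_axis",
]

#: Instrument calibration window, cm^-1 (silicon-wafer calibrated acquisition).
CALIBRATION_RANGE = (320.0, 4256.0)

_META_PREFIX = "_meta:"
_META_FIELDS = ("sample_id", "batch_id", "label", "d2o_hours")


def _default_meta() -> dict:
    return {"sample_id": "sample1", "batch_id": "batch1", "label": None, "d2o_hours": 0.0}


@dataclass(frozen=True)
class WavenumberAxis:
    """Strictly increasing wavenumber grid in cm^-1."""

    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1 or values.size < 2:
            raise ValueError("axis needs at least two wavenumber points")
        if not np.all(np.isfinite(values)):
            raise ValueError("axis contains non-finite wavenumbers")
        if not np.all(np.diff(values) > 0):
            raise ValueError("axis must be strictly increasing")
        if values[0] < CALIBRATION_RANGE[0] or values[-1] > CALIBRATION_RANGE[1]:
            warnings.warn(
                f"axis extends outside the calibration range {CALIBRATION_RANGE} cm^-1",
                UserWarning,
                stacklevel=2,
            )
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return int(self.values.size)

    def band_mask(self, lo: float, hi: float) -> np.ndarray:
        """Boolean mask of axis points with lo <= w <= hi."""
        return (self.values >= lo) & (self.values <= hi)

    def covers(self, lo: float, hi: float) -> bool:
        return bool(self.band_mask(lo, hi).any())


@dataclass(frozen=True)
class SingleCellSpectrum:
    """One cell's intensity vector (arbitrary units) plus acquisition metadata."""

    cell_id: str
    intensities: np.ndarray
    meta: dict = field(default_factory=_default_meta)

    def __post_init__(self) -> None:
        intensities = np.asarray(self.intensities, dtype=float)
        if not np.all(np.isfinite(intensities)):
            raise ValueError(f"cell {self.cell_id!r}: non-finite intensities")
        meta = {**_default_meta(), **dict(self.meta)}
        if float(meta["d2o_hours"]) < 0:
            raise ValueError(f"cell {self.cell_id!r}: d2o_hours must be >= 0")
        object.__setattr__(self, "intensities", intensities)
        object.__setattr__(self, "meta", meta)

    def with_intensities(self, values: np.ndarray) -> "SingleCellSpectrum":
        return SingleCellSpectrum(self.cell_id, np.asarray(values, dtype=float), dict(self.meta))


@dataclass(frozen=True)
class Ramanome:
    """A batch-aware SCRS collection on a shared wavenumber axis."""

    axis: WavenumberAxis
    cells: tuple
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        cells = tuple(self.cells)
        n = len(self.axis)
        ids = [c.cell_id for c in cells]
        if len(set(ids)) != len(ids):
            raise ValueError("cell_ids must be unique")
        for c in cells:
            if c.intensities.size != n:
                raise ValueError(
                    f"cell {c.cell_id!r}: {c.intensities.size} intensities on a "
                    f"{n}-point axis"
                )
        object.__setattr__(self, "cells", cells)
        object.__setattr__(self, "provenance", dict(self.provenance))

    def __len__(self) -> int:
        return len(self.cells)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def to_matrix(self) -> np.ndarray:
        """(n_cells, n_wavenumbers) intensity matrix."""
        if not self.cells:
            return np.empty((0, len(self.axis)))
        return np.vstack([c.intensities for c in self.cells])

    def cell_ids(self) -> list:
        return [c.cell_id for c in self.cells]

    def meta_values(self, key: str) -> list:
        return [c.meta.get(key) for c in self.cells]

    def labels(self) -> list:
        return self.meta_values("label")

    def batches(self) -> list:
        return sorted({c.meta.get("batch_id") for c in self.cells})

    def with_matrix(self, matrix: np.ndarray, provenance_update: Mapping | None = None) -> "Ramanome":
        """New Ramanome with the same axis/metadata and replaced intensities."""
        matrix = np.asarray(matrix, dtype=float)
        if matrix.shape != (len(self.cells), len(self.axis)):
            raise ValueError("matrix shape does not match ramanome")
        cells = tuple(c.with_intensities(row) for c, row in zip(self.cells, matrix))
        prov = dict(self.provenance)
        if provenance_update:
            prov.update(provenance_update)
        return Ramanome(self.axis, cells, prov)

    def select_cells(self, indices: Sequence[int], provenance_update: Mapping | None = None) -> "Ramanome":
        cells = tuple(self.cells[i] for i in indices)
        prov = dict(self.provenance)
        if provenance_update:
            prov.update(provenance_update)
        return Ramanome(self.axis, cells, prov)

    def subset_by(self, key: str, value) -> "Ramanome":
        idx = [i for i, c in enumerate(self.cells) if c.meta.get(key) == value]
        return self.select_cells(idx)

    def to_long_frame(self) -> pd.DataFrame:
        records = []
        w = self.axis.values
        for c in self.cells:
            df = pd.DataFrame({"cell_id": c.cell_id, "wavenumber": w, "intensity": c.intensities})
            for k in _META_FIELDS:
                df[k] = c.meta.get(k)
            records.append(df)
        if not records:
            return pd.DataFrame(columns=["cell_id", "wavenumber", "intensity", *_META_FIELDS])
        return pd.concat(records, ignore_index=True)


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".tab", ".txt") else ","


def read_spectra(path, layout: str = "wide") -> Ramanome:
    """Read a delimited-text spectra file into a :class:`Ramanome`.

    Wide layout: first column wavenumber, one column per cell (optional
    ``_meta:`` rows first).  Long layout: ``cell_id, wavenumber, intensity``
    plus optional metadata columns; rows may arrive in any order.  Cells on
    differing axes in long layout are linearly resampled onto the union grid
    (the harmonize path); in wide layout a shared axis is structural.
    """
    path = Path(path)
    if layout not in ("wide", "long"):
        raise ValueError(f"unknown layout {layout!r}")
    df = pd.read_csv(path, sep=_sep_for(path))
    if layout == "wide":
        return _ramanome_from_wide(df, str(path))
    return _ramanome_from_long(df, str(path))


def _ramanome_from_wide(df: pd.DataFrame, source: str) -> Ramanome:
    first = df.columns[0]
    meta_rows = df[df[first].astype(str).str.startswith(_META_PREFIX)]
    data = df[~df[first].astype(str).str.startswith(_META_PREFIX)].copy()
    try:
        wavenumbers = data[first].astype(float).to_numpy()
    except ValueError as exc:
        raise ValueError(f"{source}: non-numeric wavenumber column") from exc
    if pd.Series(wavenumbers).duplicated().any():
        raise ValueError(f"{source}: duplicate wavenumbers")
    order = np.argsort(wavenumbers)
    axis = WavenumberAxis(wavenumbers[order])
    meta_by_cell: dict = {}
    for _, row in meta_rows.iterrows():
        key = str(row[first])[len(_META_PREFIX):]
        for col in df.columns[1:]:
            meta_by_cell.setdefault(col, {})[key] = row[col]
    cells = []
    for col in df.columns[1:]:
        try:
            values = data[col].astype(float).to_numpy()[order]
        except ValueError as exc:
            raise ValueError(f"{source}: non-numeric intensity in column {col!r}") from exc
        meta = _default_meta()
        for k, v in meta_by_cell.get(col, {}).items():
            if k == "d2o_hours":
                v = float(v)
            elif pd.isna(v):
                v = None
            meta[k] = v
        cells.append(SingleCellSpectrum(str(col), values, meta))
    return Ramanome(axis, tuple(cells), {"source": source, "layout": "wide"})


def _ramanome_from_long(df: pd.DataFrame, source: str) -> Ramanome:
    required = {"cell_id", "wavenumber", "intensity"}
    if not required.issubset(df.columns):
        raise ValueError(f"{source}: long layout requires columns {sorted(required)}")
    per_cell: dict = {}
    metas: dict = {}
    for cell_id, grp in df.groupby("cell_id", sort=True):
        w = grp["wavenumber"].astype(float).to_numpy()
        if pd.Series(w).duplicated().any():
            raise ValueError(f"{source}: duplicate wavenumbers for cell {cell_id!r}")
        order = np.argsort(w)
        y = grp["intensity"].astype(float).to_numpy()[order]
        per_cell[str(cell_id)] = (w[order], y)
        meta = _default_meta()
        for k in _META_FIELDS:
            if k in grp.columns:
                v = grp[k].iloc[0]
                if k == "d2o_hours":
                    v = float(v)
                elif pd.isna(v):
                    v = None
                meta[k] = v
        metas[str(cell_id)] = meta
    axes = [tuple(w) for w, _ in per_cell.values()]
    if len(set(axes)) <= 1:
        axis = WavenumberAxis(np.asarray(axes[0], dtype=float)) if axes else None
        if axis is None:
            raise ValueError(f"{source}: no cells found")
        cells = [SingleCellSpectrum(cid, y, metas[cid]) for cid, (_, y) in per_cell.items()]
        return Ramanome(axis, tuple(cells), {"source": source, "layout": "long"})
    # Differing per-cell axes: resample every cell onto the union grid.
    target = WavenumberAxis(np.unique(np.concatenate([w for w, _ in per_cell.values()])))
    return harmonize_axis(
        [(cid, w, y, metas[cid]) for cid, (w, y) in per_cell.items()],
        target,
        provenance={"source": source, "layout": "long", "harmonized": True},
    )


def write_spectra(ramanome: Ramanome, path, layout: str = "wide") -> Path:
    """Write a ramanome to delimited text; inverse of :func:`read_spectra`."""
    path = Path(path)
    sep = _sep_for(path)
    if layout == "wide":
        df = pd.DataFrame({"wavenumber": ramanome.axis.values})
        for c in ramanome.cells:
            df[c.cell_id] = c.intensities
        meta_rows = []
        for key in _META_FIELDS:
            row = {"wavenumber": f"{_META_PREFIX}{key}"}
            for c in ramanome.cells:
                row[c.cell_id] = c.meta.get(key)
            meta_rows.append(row)
        out = pd.concat([pd.DataFrame(meta_rows), df], ignore_index=True)
        out.to_csv(path, sep=sep, index=False, float_format="%.12g")
    elif layout == "long":
        ramanome.to_long_frame().to_csv(path, sep=sep, index=False, float_format="%.12g")
    else:
        raise ValueError(f"unknown layout {layout!r}")
    return path


def harmonize_axis(
    cells_with_axes: Iterable,
    target_axis: WavenumberAxis,
    provenance: Mapping | None = None,
) -> Ramanome:
    """Linearly resample per-cell spectra onto ``target_axis``.

    ``cells_with_axes`` is either a :class:`Ramanome` (identity if already on
    the target axis) or an iterable of ``(cell_id, wavenumbers, intensities,
    meta)`` tuples.  Target points outside a cell's native range are set to 0
    and the cell flagged with ``meta['harmonize_zero_filled']=True``.
    """
    if isinstance(cells_with_axes, Ramanome):
        r = cells_with_axes
        if np.array_equal(r.axis.values, target_axis.values):
            return r
        items = [(c.cell_id, r.axis.values, c.intensities, c.meta) for c in r.cells]
        prov = dict(r.provenance)
    else:
        items = [
            (cid, np.asarray(w, dtype=float), np.asarray(y, dtype=float), dict(meta))
            for cid, w, y, meta in cells_with_axes
        ]
        prov = {}
    if provenance:
        prov.update(provenance)
    t = target_axis.values
    cells = []
    for cid, w, y, meta in items:
        if w[-1] < t[0] or w[0] > t[-1]:
            raise ValueError(f"cell {cid!r}: native axis does not overlap target")
        resampled = np.interp(t, w, y, left=0.0, right=0.0)
        meta = dict(meta)
        if t[0] < w[0] or t[-1] > w[-1]:
            meta["harmonize_zero_filled"] = True
        cells.append(SingleCellSpectrum(cid, resampled, meta))
    return Ramanome(target_axis, tuple(cells), prov)


def read_manifest(path) -> dict:
    """Dataset manifest JSON: sample -> files, labels, batch ids."""
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)
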