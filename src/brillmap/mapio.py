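"""Readers/writers for shift maps, label masks, cohort tables and heat maps.

Grid convention: pixel centers, micrometres, origin at the top-left pixel
center, x increasing rightward (columns), y increasing downward (rows).
CSV files are comma separated, dot decimal, UTF-8, header mandatory; float
values are serialized with ``repr`` precision so write->read round trips are
bit exact.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from matplotlib import colormaps

__all__ = [
    "LABELS",
    "ShiftMap",
    "ContrastMap",
    "LabelMask",
    "CohortTable",
    "MapFormatError",
    "read_map_csv",
    "write_map_csv",
    "read_mask_csv",
    "write_mask_csv",
    "read_cohort_csv",
    "write_cohort_csv",
    "render_heatmap",
]

#: closed set of tissue-region labels
LABELS = ("medium", "epidermis", "interstitial", "ecm", "chondrocyte", "joint")


class MapFormatError(ValueError):
    """Raised for malformed map/mask/cohort CSV files."""


@dataclass
class ShiftMap:
    """2D grid of Brillouin frequency shifts (GHz)."""

    values: np.ndarray  # (ny, nx), GHz
    pixel_um: float
    origin_um: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2D grid")
        if not np.all(np.isfinite(self.values)) or np.any(self.values <= 0):
            raise ValueError("shift values must be finite and > 0")
        if self.pixel_um <= 0:
            raise ValueError("pixel_um must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def x_coords(self) -> np.ndarray:
        return self.origin_um[0] + self.pixel_um * np.arange(self.shape[1])

    def y_coords(self) -> np.ndarray:
        return self.origin_um[1] + self.pixel_um * np.arange(self.shape[0])


@dataclass
class ContrastMap:
    """2D grid of dimensionless Brillouin elastic contrast."""

    values: np.ndarray
    pixel_um: float
    origin_um: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2D grid")
        if not np.all(np.isfinite(self.values)) or np.any(self.values <= -1):
            raise ValueError("contrast values must be finite and > -1")
        if self.pixel_um <= 0:
            raise ValueError("pixel_um must be positive")

    shape = ShiftMap.shape
    x_coords = ShiftMap.x_coords
    y_coords = ShiftMap.y_coords


@dataclass
class LabelMask:
    """Tissue-region labels on the same grid as a paired map.

    ``cell_ids`` assigns a positive integer to each chondrocyte pixel and 0
    elsewhere, identifying individual cells.
    """

    labels: np.ndarray  # (ny, nx) of strings from LABELS
    cell_ids: np.ndarray | None = None
    pixel_um: float = 1.0
    origin_um: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=object)
        if self.labels.ndim != 2:
            raise ValueError("labels must be a 2D grid")
        bad = set(np.unique(self.labels)) - set(LABELS)
        if bad:
            raise ValueError(f"unknown labels: {sorted(bad)}")
        if self.cell_ids is None:
            self.cell_ids = np.zeros(self.labels.shape, dtype=int)
        else:
            self.cell_ids = np.asarray(self.cell_ids, dtype=int)
            if self.cell_ids.shape != self.labels.shape:
                raise ValueError("cell_ids shape must match labels")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape


@dataclass
class CohortTable:
    """Long-format (animal_id, condition, value) records.

    ``conditions`` is the declared condition ordering (used by the
    repeated-measures statistics); defaults to first-appearance order.
    """

    rows: pd.DataFrame  # columns animal_id, condition, value
    conditions: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        required = ["animal_id", "condition", "value"]
        if list(self.rows.columns) != required:
            raise ValueError(f"cohort table must have columns {required}")
        dup = self.rows.duplicated(subset=["animal_id", "condition"])
        if dup.any():
            raise ValueError("duplicate (animal, condition) pair")
        if not self.conditions:
            self.conditions = tuple(dict.fromkeys(self.rows["condition"]))

    def to_matrix(self) -> tuple[np.ndarray, list[str], list[str]]:
        """Pivot to a complete subjects x conditions matrix.

        Raises ``ValueError`` on missing cells.
        """
        animals = list(dict.fromkeys(self.rows["animal_id"]))
        pivot = self.rows.pivot(index="animal_id", columns="condition", values="value")
        pivot = pivot.reindex(index=animals, columns=list(self.conditions))
        if pivot.isna().any().any():
            raise ValueError("incomplete cohort: missing (animal, condition) cells")
        return pivot.to_numpy(), animals, list(self.conditions)


# ---------------------------------------------------------------------------
# CSV lattice helpers


def _lattice_from_long(
    df: pd.DataFrame, value_cols: list[str]
) -> tuple[np.ndarray, np.ndarray, list[np.ndarray]]:
    """Arrange long-format (x, y, *values) rows into a rectangular grid."""
    xs = np.unique(df["x_um"].to_numpy())
    ys = np.unique(df["y_um"].to_numpy())
    if len(df) != len(xs) * len(ys):
        raise MapFormatError(
            f"rows do not form a complete {len(ys)}x{len(xs)} lattice "
            f"({len(df)} rows)"
        )
    for coords, name in ((xs, "x"), (ys, "y")):
        if len(coords) > 1:
            steps = np.diff(coords)
            if not np.allclose(steps, steps[0], rtol=1e-9, atol=1e-9):
                raise MapFormatError(f"non-uniform {name} lattice pitch")
    order = np.lexsort((df["x_um"].to_numpy(), df["y_um"].to_numpy()))
    grids = []
    for col in value_cols:
        grids.append(df[col].to_numpy()[order].reshape(len(ys), len(xs)))
    return xs, ys, grids


def _infer_pixel(xs: np.ndarray, ys: np.ndarray) -> float:
    candidates = []
    if len(xs) > 1:
        candidates.append(xs[1] - xs[0])
    if len(ys) > 1:
        candidates.append(ys[1] - ys[0])
    if not candidates:
        return 1.0
    if len(candidates) == 2 and not np.isclose(candidates[0], candidates[1]):
        raise MapFormatError("x and y lattice pitches differ")
    return float(candidates[0])


def _read_lattice_csv(path, expected_header: list[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, dtype=str)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise MapFormatError(str(exc)) from exc
    if list(df.columns) != expected_header:
        raise MapFormatError(
            f"expected header {','.join(expected_header)}, got {','.join(df.columns)}"
        )
    return df


def _to_float(df: pd.DataFrame, cols: list[str]) -> pd.DataFrame:
    def parse(text):  # Python float(): correctly rounded, unlike the fast
        try:  # pandas parser, so repr round trips are bit exact
            return float(text)
        except (TypeError, ValueError):
            return np.nan

    df = df.copy()
    for col in cols:
        converted = df[col].map(parse)
        bad = converted.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # 1-based + header
            raise MapFormatError(f"non-numeric value in column {col!r} at line {row}")
        df[col] = converted
    return df


def read_map_csv(path) -> ShiftMap:
    """Read a shift map from CSV with header ``x_um,y_um,shift_GHz``."""
    df = _read_lattice_csv(path, ["x_um", "y_um", "shift_GHz"])
    df = _to_float(df, ["x_um", "y_um", "shift_GHz"])
    if df.duplicated(subset=["x_um", "y_um"]).any():
        row = int(np.flatnonzero(df.duplicated(subset=["x_um", "y_um"]))[0]) + 2
        raise MapFormatError(f"duplicate lattice coordinate at line {row}")
    xs, ys, (values,) = _lattice_from_long(df, ["shift_GHz"])
    return ShiftMap(values, _infer_pixel(xs, ys), (float(xs[0]), float(ys[0])))


def write_map_csv(shift_map: ShiftMap, path) -> None:
    """Write a shift map as long-format CSV at full (repr) precision."""
    xs = shift_map.x_coords()
    ys = shift_map.y_coords()
    buf = io.StringIO()
    buf.write("x_um,y_um,shift_GHz\n")
    for iy, y in enumerate(ys):
        for ix, x in enumerate(xs):
            buf.write(
                f"{float(x)!r},{float(y)!r},{float(shift_map.values[iy, ix])!r}\n"
            )
    Path(path).write_text(buf.getvalue(), encoding="utf-8")


def read_mask_csv(path) -> LabelMask:
    """Read a label mask from CSV with header ``x_um,y_um,label,cell_id``."""
    df = _read_lattice_csv(path, ["x_um", "y_um", "label", "cell_id"])
    df = _to_float(df, ["x_um", "y_um", "cell_id"])
    bad = ~df["label"].isin(LABELS)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0]) + 2
        raise MapFormatError(f"unknown label at line {row}")
    if df.duplicated(subset=["x_um", "y_um"]).any():
        row = int(np.flatnonzero(df.duplicated(subset=["x_um", "y_um"]))[0]) + 2
        raise MapFormatError(f"duplicate lattice coordinate at line {row}")
    xs, ys, (labels, cell_ids) = _lattice_from_long(df, ["label", "cell_id"])
    return LabelMask(
        labels,
        cell_ids.astype(int),
        _infer_pixel(xs, ys),
        (float(xs[0]), float(ys[0])),
    )


def write_mask_csv(mask: LabelMask, path) -> None:
    xs = mask.origin_um[0] + mask.pixel_um * np.arange(mask.shape[1])
    ys = mask.origin_um[1] + mask.pixel_um * np.arange(mask.shape[0])
    buf = io.StringIO()
    buf.write("x_um,y_um,label,cell_id\n")
    for iy, y in enumerate(ys):
        for ix, x in enumerate(xs):
            buf.write(
                f"{float(x)!r},{float(y)!r},{mask.labels[iy, ix]},"
                f"{int(mask.cell_ids[iy, ix])}\n"
            )
    Path(path).write_text(buf.getvalue(), encoding="utf-8")


def read_cohort_csv(path, conditions: tuple[str, ...] = ()) -> CohortTable:
    """Read a cohort table from CSV with header ``animal_id,condition,value``."""
    df = pd.read_csv(path, dtype=str)
    if list(df.columns) != ["animal_id", "condition", "value"]:
        raise MapFormatError(
            f"expected header animal_id,condition,value, got {','.join(df.columns)}"
        )
    df = _to_float(df, ["value"])
    try:
        return CohortTable(df, tuple(conditions))
    except ValueError as exc:
        raise MapFormatError(str(exc)) from exc


def write_cohort_csv(table: CohortTable, path) -> None:
    buf = io.StringIO()
    buf.write("animal_id,condition,value\n")
    for row in table.rows.itertuples(index=False):
        buf.write(f"{row.animal_id},{row.condition},{float(row.value)!r}\n")
    Path(path).write_text(buf.getvalue(), encoding="utf-8")


def render_heatmap(
    contrast_map: ContrastMap,
    color_limits: tuple[float, float],
    path,
    cmap: str = "viridis",
) -> None:
    """Render a contrast map as a deterministic PNG heat map.

    Values are clamped to ``color_limits`` and mapped through a matplotlib
    colormap to 8-bit RGBA; the PNG bytes depend only on the inputs.
    """
    lo, hi = color_limits
    if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
        raise ValueError("color limits must be finite with low < high")
    if contrast_map.values.size == 0:
        raise ValueError("empty map")
    norm = np.clip((contrast_map.values - lo) / (hi - lo), 0.0, 1.0)
    rgba = (colormaps[cmap](norm) * 255).astype(np.uint8)
    iio.imwrite(Path(path), rgba, extension=".png")
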