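"""Spatial quantification of contrast maps.

ROI membership is by pixel-center inclusion in a half-open rectangle
[x, x+w) x [y, y+h).  Transversal profiles average five parallel
single-pixel lines separated by a nominal 5 um (rounded to a whole pixel
offset).  Size normalization maps the outermost above-threshold positions
to -100/+100 % with the midpoint at 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from brillmap.mapio import ContrastMap, LabelMask, ShiftMap
from brillmap.physics import OpticalConfig, shift_to_contrast

__all__ = [
    "RectROI",
    "LineProfile",
    "EDGE_THRESHOLD",
    "to_contrast_map",
    "roi_mean",
    "mask_means",
    "transversal_profiles",
    "normalize_profile",
    "digit_length_ratio",
]

log = logging.getLogger(__name__)

#: contrast of the surrounding benzocaine medium; defines structure edges
EDGE_THRESHOLD = 0.006


@dataclass(frozen=True)
class RectROI:
    """Axis-aligned rectangle in map coordinates (um)."""

    x_um: float
    y_um: float
    width_um: float
    height_um: float

    def __post_init__(self) -> None:
        if self.width_um <= 0 or self.height_um <= 0:
            raise ValueError("ROI extent must be positive")


@dataclass
class LineProfile:
    """Ordered positions with contrast values; positions in um, or in
    percent of structure half-width after normalization."""

    positions: np.ndarray
    values: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.positions.shape != self.values.shape or self.positions.ndim != 1:
            raise ValueError("positions and values must be equal-length 1D arrays")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        if self.normalized:
            if self.positions[0] < -100 - 1e-9 or self.positions[-1] > 100 + 1e-9:
                raise ValueError("normalized positions must lie in [-100, 100]")


def to_contrast_map(
    shift_map: ShiftMap, config: OpticalConfig = OpticalConfig()
) -> ContrastMap:
    """Elementwise contrast conversion; grid metadata preserved."""
    return ContrastMap(
        shift_to_contrast(shift_map.values, config),
        shift_map.pixel_um,
        shift_map.origin_um,
    )


def _roi_slices(cmap: ContrastMap, roi: RectROI) -> tuple[np.ndarray, np.ndarray]:
    xs = cmap.x_coords()
    ys = cmap.y_coords()
    in_x = (xs >= roi.x_um) & (xs < roi.x_um + roi.width_um)
    in_y = (ys >= roi.y_um) & (ys < roi.y_um + roi.height_um)
    return in_y, in_x


def roi_mean(cmap: ContrastMap, roi: RectROI) -> float:
    """Mean contrast over pixels whose centers fall inside the ROI."""
    xs, ys = cmap.x_coords(), cmap.y_coords()
    if (
        roi.x_um + roi.width_um <= xs[0]
        or roi.x_um > xs[-1]
        or roi.y_um + roi.height_um <= ys[0]
        or roi.y_um > ys[-1]
    ):
        raise ValueError("ROI lies outside the map")
    in_y, in_x = _roi_slices(cmap, roi)
    if not in_y.any() or not in_x.any():
        raise ValueError("ROI contains no pixel centers")
    return float(cmap.values[np.ix_(in_y, in_x)].mean())


def mask_means(cmap: ContrastMap, mask: LabelMask) -> dict:
    """Per-chondrocyte and per-region mean contrast.

    Returns a dict with ``cell_means`` ({cell_id: mean}), ``region_means``
    ({label: mean}, absent labels omitted), ``region_counts`` and
    ``cell_counts`` (pixel counts).  The ECM mean is
    ``region_means['ecm']`` when ECM pixels exist.
    """
    if mask.shape != cmap.values.shape:
        raise ValueError("mask shape must match map shape")
    region_means: dict[str, float] = {}
    region_counts: dict[str, int] = {}
    for label in np.unique(mask.labels):
        sel = mask.labels == label
        region_means[str(label)] = float(cmap.values[sel].mean())
        region_counts[str(label)] = int(sel.sum())
    cell_means: dict[int, float] = {}
    cell_counts: dict[int, int] = {}
    chond = mask.labels == "chondrocyte"
    for cid in np.unique(mask.cell_ids[chond]):
        if cid <= 0:
            continue
        sel = chond & (mask.cell_ids == cid)
        cell_means[int(cid)] = float(cmap.values[sel].mean())
        cell_counts[int(cid)] = int(sel.sum())
    return {
        "cell_means": cell_means,
        "cell_counts": cell_counts,
        "region_means": region_means,
        "region_counts": region_counts,
    }


def transversal_profiles(
    cmap: ContrastMap,
    anchor_um: float,
    orientation: str = "x",
    n_lines: int = 5,
    spacing_um: float = 5.0,
) -> LineProfile:
    """Average of parallel transversal lines into one profile.

    ``orientation`` is the axis the profile runs along ('x' samples rows,
    'y' samples columns); ``anchor_um`` is the center coordinate of the
    line bundle along the perpendicular axis.  Each line is one pixel wide
    (the nominal 1 um width is sub-pixel on these grids); the nominal
    spacing is rounded to a whole pixel offset and logged.
    """
    if orientation not in ("x", "y"):
        raise ValueError("orientation must be 'x' or 'y'")
    grid = cmap.values if orientation == "x" else cmap.values.T
    perp_coords = cmap.y_coords() if orientation == "x" else cmap.x_coords()
    along_coords = cmap.x_coords() if orientation == "x" else cmap.y_coords()

    step = max(1, round(spacing_um / cmap.pixel_um))
    realized = step * cmap.pixel_um
    if not np.isclose(realized, spacing_um):
        log.info("line spacing rounded from %.3g to %.3g um", spacing_um, realized)

    center_idx = int(round((anchor_um - perp_coords[0]) / cmap.pixel_um))
    offsets = (np.arange(n_lines) - (n_lines - 1) / 2.0) * step
    rows = center_idx + np.round(offsets).astype(int)
    if rows.min() < 0 or rows.max() >= grid.shape[0]:
        raise ValueError(
            f"{n_lines} lines at spacing {realized} um around {anchor_um} um "
            "exceed map bounds"
        )
    profile = grid[rows, :].mean(axis=0)
    return LineProfile(along_coords.copy(), profile, normalized=False)


def normalize_profile(
    profile: LineProfile, edge_threshold: float = EDGE_THRESHOLD
) -> LineProfile:
    """Size-normalize a profile: outermost above-threshold positions become
    -100/+100 % and their midpoint 0; values are unchanged; output is
    restricted to [-100, 100].  Idempotent on already-normalized profiles
    spanning [-100, 100].
    """
    above = np.flatnonzero(profile.values >= edge_threshold)
    if above.size < 2:
        raise ValueError(
            "no structure found: fewer than two positions at or above the "
            f"edge threshold {edge_threshold}"
        )
    left = profile.positions[above[0]]
    right = profile.positions[above[-1]]
    if right == left:
        raise ValueError("degenerate structure of zero width")
    centre = (left + right) / 2.0
    half = (right - left) / 2.0
    pos = (profile.positions - centre) / half * 100.0
    keep = (pos >= -100.0 - 1e-9) & (pos <= 100.0 + 1e-9)
    return LineProfile(
        np.clip(pos[keep], -100.0, 100.0), profile.values[keep], normalized=True
    )


def digit_length_ratio(lengths: pd.DataFrame) -> pd.DataFrame:
    """Per-digit length ratios relative to the first time point.

    ``lengths`` is long-format with columns (animal_id, digit, timepoint,
    length_um); ``digit`` distinguishes amputated from contralateral.
    Returns the same rows with a ``ratio`` column = length / length at the
    smallest timepoint of that (animal, digit).
    """
    required = {"animal_id", "digit", "timepoint", "length_um"}
    if not required.issubset(lengths.columns):
        raise ValueError(f"lengths table needs columns {sorted(required)}")
    out = lengths.copy()
    out["ratio"] = np.nan
    for (_, _), grp in out.groupby(["animal_id", "digit"]):
        t0 = grp["timepoint"].min()
        base = grp.loc[grp["timepoint"] == t0, "length_um"]
        if base.empty or (base <= 0).any():
            raise ValueError("missing or non-positive day-0 length")
        out.loc[grp.index, "ratio"] = grp["length_um"] / float(base.iloc[0])
    return out
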