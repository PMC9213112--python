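"""Synthetic tissue phantoms with known ground truth.

Renders digit-like shift maps (elongated cartilage band with oval
chondrocytes, epidermis border, interstitial space, surrounding medium)
plus matching label masks, and samples repeated-measures cohort tables.
Three series factories mimic the structure of the collagenase time course,
the developmental-stage comparison and the regeneration time course, so the
full pipeline can be exercised without external data.

Default region contrasts anchor only the medium (0.006) to a printed value;
all other magnitudes are plain choices and only their orderings matter.
All generation is a pure function of (spec, seed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from brillmap.mapio import LABELS, CohortTable, LabelMask, ShiftMap
from brillmap.physics import OpticalConfig, contrast_to_shift

__all__ = [
    "RegionSpec",
    "PhantomSpec",
    "CohortSpec",
    "GenerationError",
    "render_digit_phantom",
    "collagenase_series",
    "development_series",
    "regeneration_series",
    "digit_length_model",
    "sample_cohort",
    "mature_digit_spec",
    "expected_region_means",
    "expected_map_mean",
    "DEVELOPMENT_STAGES",
]

log = logging.getLogger(__name__)

DEVELOPMENT_STAGES = (45, 47, 49, 51, 53)


class GenerationError(RuntimeError):
    """Raised when a phantom cannot be generated under its constraints."""


@dataclass(frozen=True)
class RegionSpec:
    """Contrast distribution of one tissue region."""

    label: str
    mean_contrast: float
    sd_contrast: float = 0.0

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"unknown label {self.label!r}")
        if self.sd_contrast < 0:
            raise ValueError("sd must be non-negative")
        if self.mean_contrast <= -1:
            raise ValueError("mean contrast must be > -1")


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and contrast specification of one digit phantom.

    The tissue is a horizontal band: medium margins top and bottom, then an
    epidermis layer, an interstitial layer, and a central cartilage band
    (ECM with embedded oval chondrocytes).  When no ``ecm`` region is
    declared the interior is homogeneous interstitial tissue (early limb
    bud).  An optional ``joint`` region is a vertical strip through the
    cartilage band.
    """

    width_um: float = 148.0
    height_um: float = 80.0
    pixel_um: float = 2.0
    regions: tuple[RegionSpec, ...] = ()
    cell_count: int = 12
    cell_radii_um: tuple[float, float] = (5.0, 4.0)
    epidermis_thickness_um: float = 6.0
    interstitial_thickness_um: float = 6.0
    medium_margin_um: float = 8.0
    joint_center_x_um: float | None = None
    joint_width_um: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("width_um", "height_um"):
            extent = getattr(self, name)
            if extent <= 0 or not np.isclose(
                round(extent / self.pixel_um) * self.pixel_um, extent
            ):
                raise ValueError(f"{name} must be a positive multiple of pixel_um")
        if self.cell_count < 0:
            raise ValueError("cell_count must be non-negative")
        if min(self.cell_radii_um) <= 0:
            raise ValueError("cell radii must be positive")
        labels = [r.label for r in self.regions]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate region labels")

    def region(self, label: str) -> RegionSpec | None:
        for r in self.regions:
            if r.label == label:
                return r
        return None

    @property
    def shape(self) -> tuple[int, int]:
        return (
            int(round(self.height_um / self.pixel_um)),
            int(round(self.width_um / self.pixel_um)),
        )


@dataclass(frozen=True)
class CohortSpec:
    """Repeated-measures cohort: per-condition fixed effects plus Gaussian
    animal and residual effects."""

    n_animals: int
    conditions: tuple[str, ...]
    condition_effects: tuple[float, ...]
    animal_sd: float = 0.0
    residual_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_animals < 2:
            raise ValueError("need at least 2 animals")
        if len(self.conditions) < 2:
            raise ValueError("need at least 2 conditions")
        if len(self.condition_effects) != len(self.conditions):
            raise ValueError("one effect per condition required")
        if self.animal_sd < 0 or self.residual_sd < 0:
            raise ValueError("sds must be non-negative")


# ---------------------------------------------------------------------------
# default specs


def _mature_regions(
    ecm: float = 0.060, chondrocyte: float = 0.045, sd: float = 0.004
) -> tuple[RegionSpec, ...]:
    return (
        RegionSpec("medium", 0.006, 0.002),
        RegionSpec("epidermis", 0.030, 0.003),
        RegionSpec("interstitial", 0.020, 0.003),
        RegionSpec("ecm", ecm, sd),
        RegionSpec("chondrocyte", chondrocyte, sd),
    )


def mature_digit_spec(seed: int = 0) -> PhantomSpec:
    """Default mature-digit phantom: ECM stiffer than chondrocytes."""
    return PhantomSpec(regions=_mature_regions(), seed=seed)


# ---------------------------------------------------------------------------
# rendering


def _band_rows(spec: PhantomSpec) -> tuple[int, int]:
    """Row index range [lo, hi) of the central cartilage band."""
    ny, _ = spec.shape
    margin = int(round(spec.medium_margin_um / spec.pixel_um))
    epi = int(round(spec.epidermis_thickness_um / spec.pixel_um))
    inter = int(round(spec.interstitial_thickness_um / spec.pixel_um))
    lo = margin + epi + inter
    hi = ny - lo
    if hi <= lo:
        raise GenerationError("layers leave no room for the cartilage band")
    return lo, hi


def _render_labels(spec: PhantomSpec, rng: np.random.Generator) -> LabelMask:
    ny, nx = spec.shape
    labels = np.full((ny, nx), "medium", dtype=object)
    cell_ids = np.zeros((ny, nx), dtype=int)

    margin = int(round(spec.medium_margin_um / spec.pixel_um))
    epi = int(round(spec.epidermis_thickness_um / spec.pixel_um))
    lo, hi = _band_rows(spec)

    labels[margin : ny - margin, :] = "interstitial"
    labels[margin : margin + epi, :] = "epidermis"
    labels[ny - margin - epi : ny - margin, :] = "epidermis"

    has_ecm = spec.region("ecm") is not None
    if has_ecm:
        labels[lo:hi, :] = "ecm"
        if spec.joint_center_x_um is not None and spec.region("joint") is not None:
            xs = spec.pixel_um * np.arange(nx)
            in_joint = (
                np.abs(xs - spec.joint_center_x_um) <= spec.joint_width_um / 2.0
            )
            labels[lo:hi, in_joint] = "joint"

    if spec.cell_count > 0:
        if not has_ecm:
            raise GenerationError("chondrocytes require an ecm region")
        _place_cells(spec, labels, cell_ids, lo, hi, rng)

    return LabelMask(labels, cell_ids, spec.pixel_um)


def _place_cells(
    spec: PhantomSpec,
    labels: np.ndarray,
    cell_ids: np.ndarray,
    lo: int,
    hi: int,
    rng: np.random.Generator,
) -> None:
    """Non-overlapping oval chondrocytes on a jittered lattice in the band."""
    rx, ry = spec.cell_radii_um
    band_top = lo * spec.pixel_um
    band_bot = hi * spec.pixel_um
    band_mid = (band_top + band_bot) / 2.0
    y_slack = max(0.0, (band_bot - band_top) / 2.0 - ry - spec.pixel_um)
    n = spec.cell_count
    pitch = spec.width_um / n
    if pitch < 2 * rx + spec.pixel_um:
        raise GenerationError(
            f"cannot fit {n} cells of semi-axis {rx} um in width {spec.width_um} um"
        )
    ny, nx = labels.shape
    xg = spec.pixel_um * np.arange(nx)[None, :]
    yg = spec.pixel_um * np.arange(ny)[:, None]
    placed: list[tuple[float, float]] = []
    for i in range(n):
        for _attempt in range(100):
            cx = (i + 0.5) * pitch + rng.uniform(-0.5, 0.5) * spec.pixel_um
            cy = band_mid + rng.uniform(-1.0, 1.0) * y_slack
            if cx - rx < 0 or cx + rx > spec.width_um:
                continue
            if any(
                abs(cx - px) < 2 * rx and abs(cy - py) < 2 * ry
                for px, py in placed
            ):
                continue
            inside = ((xg - cx) / rx) ** 2 + ((yg - cy) / ry) ** 2 <= 1.0
            inside &= labels == "ecm"  # never overwrite joints or borders
            if not inside.any():
                continue
            labels[inside] = "chondrocyte"
            cell_ids[inside] = i + 1
            placed.append((cx, cy))
            break
        else:
            raise GenerationError(
                f"failed to place chondrocyte {i + 1}/{n} without overlap"
            )


def render_digit_phantom(
    spec: PhantomSpec, config: OpticalConfig = OpticalConfig()
) -> tuple[ShiftMap, LabelMask]:
    """Render a phantom to a shift map and its ground-truth label mask.

    Per-pixel shift = contrast_to_shift(region mean + Gaussian noise);
    deterministic for a fixed ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    mask = _render_labels(spec, rng)
    contrast = np.empty(mask.shape, dtype=float)
    for label in np.unique(mask.labels):
        region = spec.region(str(label))
        if region is None:
            raise GenerationError(f"no RegionSpec for rendered label {label!r}")
        sel = mask.labels == label
        noise = rng.standard_normal(int(sel.sum())) * region.sd_contrast
        contrast[sel] = region.mean_contrast + noise
    shift = contrast_to_shift(np.maximum(contrast, -0.99), config)
    return ShiftMap(shift, spec.pixel_um), mask


def expected_region_means(spec: PhantomSpec) -> dict[str, float]:
    return {r.label: r.mean_contrast for r in spec.regions}


def expected_map_mean(spec: PhantomSpec) -> float:
    """Area-weighted expected contrast of the whole map (noise-free).

    Uses the realized label geometry, so it accounts for the actual pixel
    areas of every region including placed cells.
    """
    mask = _render_labels(spec, np.random.default_rng(spec.seed))
    means = expected_region_means(spec)
    total = 0.0
    for label, count in zip(*np.unique(mask.labels, return_counts=True)):
        total += means[str(label)] * count
    return total / mask.labels.size


# ---------------------------------------------------------------------------
# experiment series


def _with_region_means(
    spec: PhantomSpec, means: dict[str, float], sds: dict[str, float] | None = None
) -> PhantomSpec:
    regions = []
    seen = set()
    for r in spec.regions:
        seen.add(r.label)
        regions.append(
            replace(
                r,
                mean_contrast=means.get(r.label, r.mean_contrast),
                sd_contrast=(sds or {}).get(r.label, r.sd_contrast),
            )
        )
    for label, mean in means.items():
        if label not in seen:
            regions.append(RegionSpec(label, mean, (sds or {}).get(label, 0.004)))
    return replace(spec, regions=tuple(regions))


#: per-time region means for the collagenase time course (minutes)
COLLAGENASE_EFFECTS: dict[int, dict[str, float]] = {
    0: {},
    30: {"ecm": 0.045, "interstitial": 0.016},
    45: {"ecm": 0.032, "interstitial": 0.013, "chondrocyte": 0.050},
}


def collagenase_series(
    base: PhantomSpec,
    times: tuple[int, ...] = (0, 30, 45),
    overrides: dict[int, dict[str, float]] | None = None,
) -> list[PhantomSpec]:
    """Phantom specs for the enzymatic-digestion time course.

    ECM softens monotonically with incubation time; at 45 min the
    remaining cells round up (equal oval axes), become slightly stiffer and
    fewer.  User overrides that break the monotone ECM ordering are kept
    but logged as a warning.
    """
    if base.region("ecm") is None:
        raise ValueError("base must be a mature digit spec with an ecm region")
    known = sorted(COLLAGENASE_EFFECTS)
    if any(t not in known for t in times):
        raise ValueError(f"times must be drawn from {known}")
    specs = []
    for t in times:
        means = dict(COLLAGENASE_EFFECTS[t])
        if overrides and t in overrides:
            means.update(overrides[t])
        spec = _with_region_means(base, means)
        if t == 45:
            r = min(base.cell_radii_um)
            spec = replace(
                spec,
                cell_count=max(1, base.cell_count * 2 // 3),
                cell_radii_um=(r, r),
            )
        specs.append(spec)
    ecm_means = [s.region("ecm").mean_contrast for s in specs]
    order = [ecm_means[i] for i in np.argsort(times)]
    if any(b >= a for a, b in zip(order, order[1:])):
        log.warning("ECM means are not strictly decreasing in time: %s", ecm_means)
    return specs


#: per-stage cartilage interior means (only orderings are meaningful)
DEVELOPMENT_EFFECTS: dict[int, float] = {
    45: 0.015,
    47: 0.022,
    49: 0.030,
    51: 0.038,
    53: 0.046,
}
_DEV_EPIDERMIS_UM = {45: 5.0, 47: 5.0, 49: 5.0, 51: 10.0, 53: 10.0}


def development_series(
    stages: tuple[int, ...] = DEVELOPMENT_STAGES, seed: int = 0
) -> list[PhantomSpec]:
    """Phantom specs across developmental stages.

    Stage 45 is a homogeneous bud with no distinct cartilage; later stages
    gain a cartilage band whose mean contrast rises with stage, with
    chondrocytes stiffer than their ECM (the developing-tissue inversion).
    Stage 53 adds a joint strip of locally elevated contrast.
    """
    if list(stages) != sorted(stages):
        raise ValueError("stages must be sorted ascending")
    if any(s not in DEVELOPMENT_EFFECTS for s in stages):
        raise ValueError(f"unknown stage; choose from {sorted(DEVELOPMENT_EFFECTS)}")
    specs = []
    for stage in stages:
        m = DEVELOPMENT_EFFECTS[stage]
        regions = [
            RegionSpec("medium", 0.006, 0.002),
            RegionSpec("epidermis", 0.018 + (stage - 45) * 0.001, 0.003),
        ]
        if stage == 45:
            regions.append(RegionSpec("interstitial", m, 0.003))
            spec = PhantomSpec(
                width_um=150.0,
                height_um=100.0,
                pixel_um=5.0,
                regions=tuple(regions),
                cell_count=0,
                epidermis_thickness_um=_DEV_EPIDERMIS_UM[stage],
                interstitial_thickness_um=5.0,
                medium_margin_um=10.0,
                seed=seed + stage,
            )
        else:
            regions.append(RegionSpec("interstitial", 0.012, 0.003))
            regions.append(RegionSpec("ecm", m, 0.004))
            regions.append(RegionSpec("chondrocyte", m + 0.010, 0.004))
            joint = stage >= 53
            if joint:
                regions.append(RegionSpec("joint", m + 0.015, 0.004))
            spec = PhantomSpec(
                width_um=150.0,
                height_um=100.0,
                pixel_um=5.0,
                regions=tuple(regions),
                cell_count=5,
                cell_radii_um=(10.0, 6.0),
                epidermis_thickness_um=_DEV_EPIDERMIS_UM[stage],
                interstitial_thickness_um=5.0,
                medium_margin_um=10.0,
                joint_center_x_um=75.0 if joint else None,
                joint_width_um=10.0,
                seed=seed + stage,
            )
        specs.append(spec)
    return specs


#: per-dpa (ecm, chondrocyte) means; at 15 dpa the two are indistinguishable
REGENERATION_EFFECTS: dict[int, tuple[float, float]] = {
    0: (0.060, 0.045),
    15: (0.030, 0.030),
    30: (0.050, 0.042),
}


def regeneration_series(
    dpas: tuple[int, ...] = (0, 15, 30),
    n_animals: int = 4,
    seed: int = 0,
) -> tuple[list[PhantomSpec], pd.DataFrame]:
    """Phantom specs plus a digit-length model for the regeneration course.

    Cartilage contrast dips at 15 dpa (no ECM/cell distinction) and
    partially recovers by 30 dpa, keeping mean(15) < mean(30) < mean(0).
    The second return value is the per-animal digit-length table from
    :func:`digit_length_model`.
    """
    if list(dpas) != sorted(dpas):
        raise ValueError("dpas must be sorted ascending")
    if any(d not in REGENERATION_EFFECTS for d in dpas):
        raise ValueError(f"unknown dpa; choose from {sorted(REGENERATION_EFFECTS)}")
    specs = []
    for dpa in dpas:
        ecm, chond = REGENERATION_EFFECTS[dpa]
        spec = PhantomSpec(
            width_um=200.0,
            height_um=80.0,
            pixel_um=2.5,
            regions=_mature_regions(ecm=ecm, chondrocyte=chond),
            cell_count=10 if dpa != 15 else 6,
            cell_radii_um=(6.0, 4.0),
            epidermis_thickness_um=7.5,
            interstitial_thickness_um=7.5,
            medium_margin_um=7.5,
            seed=seed + dpa,
        )
        specs.append(spec)
    lengths = digit_length_model(dpas, n_animals=n_animals, seed=seed)
    return specs, lengths


def digit_length_model(
    dpas: tuple[int, ...] = (0, 15, 30),
    n_animals: int = 4,
    base_length_um: float = 300.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-animal digit lengths for amputated and contralateral digits.

    Contralateral digits grow slowly; amputated digits are short at 15 dpa
    and regrow by 30 dpa while staying below the contralateral ratio.
    Columns: animal_id, digit, timepoint, length_um.
    """
    amput_ratio = {0: 1.0, 15: 0.40, 30: 0.80}
    contra_ratio = {0: 1.0, 15: 1.05, 30: 1.10}
    rng = np.random.default_rng(seed)
    rows = []
    for a in range(n_animals):
        base = base_length_um * (1.0 + 0.1 * rng.standard_normal())
        for digit, ratios in (("amputated", amput_ratio), ("contralateral", contra_ratio)):
            for dpa in dpas:
                jitter = 1.0 + 0.02 * rng.standard_normal() if dpa > 0 else 1.0
                rows.append(
                    {
                        "animal_id": f"A{a + 1}",
                        "digit": digit,
                        "timepoint": dpa,
                        "length_um": base * ratios[dpa] * jitter,
                    }
                )
    return pd.DataFrame(rows)


def sample_cohort(spec: CohortSpec) -> CohortTable:
    """Sample a long-format cohort table from the random-effects model.

    value(animal, condition) = condition effect + animal effect +
    residual, with the animal effect shared across that animal's
    conditions (repeated measures).  Seeds are split per animal so partial
    reruns stay reproducible.
    """
    seeds = np.random.SeedSequence(spec.seed).spawn(spec.n_animals)
    rows = []
    for a, ss in enumerate(seeds):
        rng = np.random.default_rng(ss)
        animal_effect = rng.standard_normal() * spec.animal_sd
        for cond, effect in zip(spec.conditions, spec.condition_effects):
            value = effect + animal_effect + rng.standard_normal() * spec.residual_sd
            rows.append(
                {"animal_id": f"A{a + 1}", "condition": cond, "value": value}
            )
    return CohortTable(pd.DataFrame(rows), tuple(spec.conditions))
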