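"""End-to-end orchestration of the three phantom studies.

Each ``run_*`` function generates per-animal phantoms, quantifies them,
runs the matching statistics and returns a report bundle that
:func:`write_report` serializes to a deterministic file tree::

    outdir/
      maps/      one CSV + mask CSV + PNG heat map per rendered map
      cohorts/   cohort tables (CSV)
      tables/    auxiliary tables, e.g. digit lengths (CSV)
      stats/     one TestResult JSON per declared comparison
      log.txt    seeds, package version, realized parameters

Per-animal variation is a Gaussian offset added to every tissue region's
mean (shared across conditions, i.e. a repeated-measures random effect),
with seeds split deterministically from the run seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

import brillmap
from brillmap.mapio import (
    CohortTable,
    ContrastMap,
    LabelMask,
    ShiftMap,
    render_heatmap,
    write_cohort_csv,
    write_map_csv,
    write_mask_csv,
)
from brillmap.phantoms import (
    PhantomSpec,
    collagenase_series,
    development_series,
    mature_digit_spec,
    regeneration_series,
    render_digit_phantom,
)
from brillmap.physics import OpticalConfig
from brillmap.quantify import (
    RectROI,
    digit_length_ratio,
    normalize_profile,
    roi_mean,
    to_contrast_map,
    transversal_profiles,
)
from brillmap.stats import (
    GroupSamples,
    RepeatedMeasuresTable,
    TestResult,
    friedman,
    kruskal_wallis,
    mann_whitney_exact,
)

__all__ = [
    "ExperimentConfig",
    "run_collagenase",
    "run_development",
    "run_regeneration",
    "run_experiment",
    "write_report",
]

log = logging.getLogger(__name__)

EXPERIMENTS = ("collagenase", "development", "regeneration")

#: default per-stage animal counts for the development study (total 23)
DEV_ANIMAL_COUNTS = {45: 5, 47: 5, 49: 5, 51: 4, 53: 4}


@dataclass(frozen=True)
class ExperimentConfig:
    """Parameters of one orchestrated phantom study."""

    experiment: str
    seed: int = 0
    n_animals: int | None = None  # None -> study default (5 / per-stage / 4)
    animal_sd: float = 0.002
    times_min: tuple[int, ...] = (0, 30, 45)
    stages: tuple[int, ...] = (45, 47, 49, 51, 53)
    dpas: tuple[int, ...] = (0, 15, 30)
    color_limits: tuple[float, float] = (0.0, 0.08)
    optical: OpticalConfig = field(default_factory=OpticalConfig)

    def __post_init__(self) -> None:
        if self.experiment not in EXPERIMENTS:
            raise ValueError(f"experiment must be one of {EXPERIMENTS}")
        if self.n_animals is not None and self.n_animals < 2:
            raise ValueError("need at least 2 animals")
        if self.animal_sd < 0:
            raise ValueError("animal_sd must be non-negative")

    @classmethod
    def from_dict(cls, experiment: str, tree: dict) -> "ExperimentConfig":
        """Build a config from a (YAML-style) key tree."""
        opt = tree.get("optical", {})
        optical = OpticalConfig(
            wavelength_lambda0=opt.get("lambda0_nm", 780.24),
            scattering_angle_theta=opt.get("theta_deg", 180.0),
            water_shift_nuB_water=opt.get("water_shift_ghz", 5.066),
        )
        kwargs = {
            k: tree[k]
            for k in (
                "seed",
                "n_animals",
                "animal_sd",
            )
            if k in tree
        }
        for k, target in (
            ("times_min", "times_min"),
            ("stages", "stages"),
            ("dpas", "dpas"),
            ("color_limits", "color_limits"),
        ):
            if k in tree:
                kwargs[target] = tuple(tree[k])
        return cls(experiment=experiment, optical=optical, **kwargs)


def _offset_spec(spec: PhantomSpec, offset: float, seed: int) -> PhantomSpec:
    """Shift every tissue region's mean by the animal offset; medium fixed."""
    regions = tuple(
        r if r.label == "medium" else replace(r, mean_contrast=r.mean_contrast + offset)
        for r in spec.regions
    )
    return replace(spec, regions=regions, seed=seed)


def _animal_streams(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _new_bundle(config: ExperimentConfig) -> dict:
    return {
        "experiment": config.experiment,
        "seed": config.seed,
        "color_limits": config.color_limits,
        "maps": {},  # name -> (ShiftMap, LabelMask, ContrastMap)
        "cohorts": {},  # name -> CohortTable
        "tables": {},  # name -> DataFrame
        "profiles": {},  # name -> DataFrame (position, value)
        "tests": {},  # name -> TestResult
        "log": [
            f"package_version={brillmap.__version__}",
            f"experiment={config.experiment}",
            f"seed={config.seed}",
        ],
    }


def run_collagenase(config: ExperimentConfig) -> dict:
    """Collagenase time course: whole-map means, Friedman + Dunn + W."""
    n_animals = config.n_animals or 5
    base = mature_digit_spec()
    series = collagenase_series(base, config.times_min)
    conditions = tuple(f"{t} min" for t in config.times_min)
    bundle = _new_bundle(config)
    rows = []
    for a, rng in enumerate(_animal_streams(config.seed, n_animals)):
        offset = float(rng.normal(0.0, config.animal_sd))
        bundle["log"].append(f"animal=A{a + 1} offset={offset:.6g}")
        for t, spec in zip(config.times_min, series):
            spec_a = _offset_spec(spec, offset, int(rng.integers(2**31)))
            smap, mask = render_digit_phantom(spec_a, config.optical)
            cmap = to_contrast_map(smap, config.optical)
            name = f"A{a + 1}_t{t:02d}min"
            bundle["maps"][name] = (smap, mask, cmap)
            rows.append(
                {
                    "animal_id": f"A{a + 1}",
                    "condition": f"{t} min",
                    "value": float(cmap.values.mean()),
                }
            )
    cohort = CohortTable(pd.DataFrame(rows), conditions)
    bundle["cohorts"]["collagenase_map_means"] = cohort
    matrix, _, conds = cohort.to_matrix()
    bundle["tests"]["friedman_map_means"] = friedman(
        RepeatedMeasuresTable(matrix, conditions=tuple(conds))
    )
    return bundle


def run_development(config: ExperimentConfig) -> dict:
    """Development stages: ROI means + normalized profiles, KW + Dunn + eta2."""
    specs = development_series(config.stages, seed=config.seed)
    bundle = _new_bundle(config)
    roi = RectROI(25.0, 0.0, 100.0, 100.0)
    bundle["log"].append("roi=100x100um at (25,0)")
    rows = []
    group_values = []
    for stage, stage_spec in zip(config.stages, specs):
        n_animals = config.n_animals or DEV_ANIMAL_COUNTS[stage]
        stage_means = []
        profile_rows = []
        for a, rng in enumerate(
            _animal_streams(config.seed * 1000 + stage, n_animals)
        ):
            offset = float(rng.normal(0.0, config.animal_sd))
            spec_a = _offset_spec(stage_spec, offset, int(rng.integers(2**31)))
            smap, mask = render_digit_phantom(spec_a, config.optical)
            cmap = to_contrast_map(smap, config.optical)
            name = f"stage{stage}_A{a + 1}"
            bundle["maps"][name] = (smap, mask, cmap)
            mean = roi_mean(cmap, roi)
            stage_means.append(mean)
            rows.append(
                {"animal_id": f"A{a + 1}", "condition": str(stage), "value": mean}
            )
            profile = normalize_profile(
                transversal_profiles(cmap, anchor_um=cmap.x_coords().mean(), orientation="y")
            )
            profile_rows.append(
                pd.DataFrame(
                    {
                        "animal_id": f"A{a + 1}",
                        "position_pct": profile.positions,
                        "value": profile.values,
                    }
                )
            )
        profiles = pd.concat(profile_rows, ignore_index=True)
        # representative animal: median whole-profile mean
        means_by_animal = profiles.groupby("animal_id")["value"].mean().sort_values()
        representative = means_by_animal.index[len(means_by_animal) // 2]
        bundle["log"].append(f"stage={stage} representative={representative}")
        bundle["profiles"][f"stage{stage}_profiles"] = profiles
        bundle["profiles"][f"stage{stage}_representative"] = profiles[
            profiles["animal_id"] == representative
        ].reset_index(drop=True)
        group_values.append(np.array(stage_means))
    cohort = CohortTable(
        pd.DataFrame(rows), tuple(str(s) for s in config.stages)
    )
    bundle["cohorts"]["development_roi_means"] = cohort
    bundle["tests"]["kruskal_wallis_roi_means"] = kruskal_wallis(
        GroupSamples(tuple(group_values), tuple(str(s) for s in config.stages))
    )
    return bundle


def run_regeneration(config: ExperimentConfig) -> dict:
    """Regeneration: cartilage ROI Friedman + digit-length Mann-Whitney."""
    n_animals = config.n_animals or 4
    specs, lengths = regeneration_series(config.dpas, n_animals, config.seed)
    conditions = tuple(f"{d} dpa" for d in config.dpas)
    bundle = _new_bundle(config)
    # 25x25 um square centred in the cartilage band
    roi = RectROI(87.5, 27.5, 25.0, 25.0)
    bundle["log"].append("roi=25x25um at (87.5,27.5)")
    rows = []
    for a, rng in enumerate(_animal_streams(config.seed, n_animals)):
        offset = float(rng.normal(0.0, config.animal_sd))
        for dpa, spec in zip(config.dpas, specs):
            spec_a = _offset_spec(spec, offset, int(rng.integers(2**31)))
            smap, mask = render_digit_phantom(spec_a, config.optical)
            cmap = to_contrast_map(smap, config.optical)
            name = f"A{a + 1}_dpa{dpa:02d}"
            bundle["maps"][name] = (smap, mask, cmap)
            rows.append(
                {
                    "animal_id": f"A{a + 1}",
                    "condition": f"{dpa} dpa",
                    "value": roi_mean(cmap, roi),
                }
            )
    cohort = CohortTable(pd.DataFrame(rows), conditions)
    bundle["cohorts"]["regeneration_roi_means"] = cohort
    matrix, _, conds = cohort.to_matrix()
    bundle["tests"]["friedman_roi_means"] = friedman(
        RepeatedMeasuresTable(matrix, conditions=tuple(conds))
    )
    ratios = digit_length_ratio(lengths)
    bundle["tables"]["digit_length_ratios"] = ratios
    for dpa in config.dpas:
        if dpa == 0:
            continue
        at_t = ratios[ratios["timepoint"] == dpa]
        amputated = at_t.loc[at_t["digit"] == "amputated", "ratio"].to_numpy()
        contralateral = at_t.loc[
            at_t["digit"] == "contralateral", "ratio"
        ].to_numpy()
        bundle["tests"][f"mann_whitney_length_{dpa}dpa"] = mann_whitney_exact(
            amputated, contralateral
        )
    return bundle


_RUNNERS = {
    "collagenase": run_collagenase,
    "development": run_development,
    "regeneration": run_regeneration,
}


def run_experiment(config: ExperimentConfig) -> dict:
    return _RUNNERS[config.experiment](config)


def write_report(bundle: dict, outdir) -> Path:
    """Serialize a report bundle to a deterministic file tree."""
    outdir = Path(outdir)
    for sub in ("maps", "cohorts", "tables", "profiles", "stats"):
        (outdir / sub).mkdir(parents=True, exist_ok=True)
    lo, hi = bundle["color_limits"]
    for name in sorted(bundle["maps"]):
        smap, mask, cmap = bundle["maps"][name]
        write_map_csv(smap, outdir / "maps" / f"{name}.csv")
        write_mask_csv(mask, outdir / "maps" / f"{name}_mask.csv")
        render_heatmap(cmap, (lo, hi), outdir / "maps" / f"{name}.png")
    for name in sorted(bundle["cohorts"]):
        write_cohort_csv(bundle["cohorts"][name], outdir / "cohorts" / f"{name}.csv")
    for name in sorted(bundle["tables"]):
        bundle["tables"][name].to_csv(outdir / "tables" / f"{name}.csv", index=False)
    for name in sorted(bundle["profiles"]):
        bundle["profiles"][name].to_csv(
            outdir / "profiles" / f"{name}.csv", index=False
        )
    for name in sorted(bundle["tests"]):
        result: TestResult = bundle["tests"][name]
        (outdir / "stats" / f"{name}.json").write_text(
            json.dumps(result.to_dict(), indent=2, sort_keys=True) + "\n",
            encoding="utf-8",
        )
    (outdir / "log.txt").write_text("\n".join(bundle["log"]) + "\n", encoding="utf-8")
    return outdir
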