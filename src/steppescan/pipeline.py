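"""End-to-end orchestration: simulate-or-load, indices, extraction, CSR
checks, pre-screen, scan, models, figures.

A run is driven by a :class:`RunConfig` (loadable from a YAML file) and
writes a run directory with per-stratum CSVs, optional figures, and a
manifest recording the seed, configuration hash and package version, so
every number in every output is reproducible from the manifest alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .buffers import ScaleGrid, extract_cube, make_scale_grid
from .indices import DEFAULT_INDICES, compute_index
from .models import per_scale_models
from .pointpattern import quadrat_test
from .scan import correlation_scan, prescreen_indices, variance_profile
from .scene import RasterScene
from .sceneio import read_scene, read_sites, write_cube, write_scene, write_sites
from .synthetic import PlantSpec, SceneSpec, generate_reflectance_scene, generate_sites, plant_trap_samples

log = logging.getLogger("steppescan")


@dataclass
class RunConfig:
    """Declarative description of one pipeline run."""

    rasters: dict[str, str] = field(default_factory=dict)  # date -> GeoTIFF path
    sites: str = ""
    site_columns: dict[str, str] = field(default_factory=dict)
    indices: tuple[str, ...] = DEFAULT_INDICES
    scale_min: float = 25.0
    scale_max: float = 1500.0
    scale_step: float = 25.0
    extraction_rule: str = "center"
    allow_edge: bool = False
    prescreen_threshold: float = 0.9
    prescreen_reference: str = "NDVI"
    prescreen_keep: tuple[str, ...] = ("TC-W", "NDWI2", "MNDWI", "SATVI", "TC-B")
    vif_threshold: float = 10.0
    stepwise_direction: str = "both"
    stepwise_criterion: str = "AIC"
    quadrat_nx: int = 5
    quadrat_ny: int = 5
    alpha: float = 0.05
    make_figures: bool = True
    out_dir: str = "run"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("indices", "prescreen_keep"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def config_hash(self) -> str:
        blob = json.dumps(
            {k: list(v) if isinstance(v, tuple) else v for k, v in self.__dict__.items()},
            sort_keys=True,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def scale_grid_from_config(config: RunConfig) -> ScaleGrid:
    return make_scale_grid(config.scale_min, config.scale_max, config.scale_step)


# ---------------------------------------------------------------------------
# fixture simulation (miniature study design)

#: stratum -> (n_sites, (xmin, ymin, xmax, ymax)); windows keep a 1500 m
#: margin inside the 13200 x 6900 m fixture scene so the full 25-1500 m
#: scale grid is extractable for every site.
FIXTURE_STRATA: dict[str, tuple[int, tuple[float, float, float, float]]] = {
    "desert": (15, (1500.0, 1500.0, 3600.0, 5400.0)),
    "typical": (45, (4100.0, 1500.0, 7600.0, 5400.0)),
    "meadow": (30, (8100.0, 1500.0, 11700.0, 5400.0)),
}
FIXTURE_DATES = ("2017-05", "2017-09")
FIXTURE_MIN_SEP = 150.0


def simulate_study(
    out_dir: str | Path,
    seed: int = 0,
    plant: PlantSpec | None = None,
    n_traps: int = 5,
    n_visits: int = 5,
    corr_length: float = 300.0,
) -> dict:
    """Emit a complete miniature study mirroring the sampling design.

    Two acquisition dates over one 440 x 230 pixel scene (30 m pixels),
    three strata with 15 / 45 / 30 sites (90 total) at >= 150 m separation,
    and trap-level counts (5 traps x 5 visits per site = 2250 trap-samples)
    pooled by summation into site abundances.  The abundance response is
    planted on one index at one radius (default: NDVI at 300 m on the May
    scene) so the downstream scan has a known scale of effect to find.

    Writes ``scene_<date>.tif``, ``sites.csv``, ``trap_samples.csv`` and
    ``ground_truth.json``; returns a manifest dict.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    scene_seed = int(rng.integers(2**31 - 1))
    site_seed = int(rng.integers(2**31 - 1))
    plant_seed = int(rng.integers(2**31 - 1))
    if plant is None:
        plant = PlantSpec(
            index_name="NDVI", radius_star=300.0, beta0=40.0, beta1=600.0, sigma=12.0,
            seed=plant_seed,
        )
    scenes = {}
    for i, date in enumerate(FIXTURE_DATES):
        spec = SceneSpec(
            n_rows=230, n_cols=440, pixel_size=30.0, origin_x=0.0, origin_y=6900.0,
            corr_length=corr_length, seed=scene_seed + i, date=date,
            date_offset=0.0 if i == 0 else -0.5,
        )
        scenes[date] = generate_reflectance_scene(spec)
        write_scene(out / f"scene_{date}.tif", scenes[date])
    frames = []
    for j, (stratum, (n, window)) in enumerate(FIXTURE_STRATA.items()):
        frames.append(
            generate_sites(
                n, window, pattern="csr", min_sep=FIXTURE_MIN_SEP,
                seed=site_seed + j, stratum=stratum,
            )
        )
    sites = pd.concat(frames, ignore_index=True)
    traps, pooled = plant_trap_samples(
        scenes[FIXTURE_DATES[0]], sites, plant, n_traps=n_traps, n_dates=n_visits,
        scales=make_scale_grid(),
    )
    write_sites(out / "sites.csv", pooled)
    traps.to_csv(out / "trap_samples.csv", index=False)
    truth = {
        "planted_index": plant.index_name,
        "radius_star": plant.radius_star,
        "beta0": plant.beta0,
        "beta1": plant.beta1,
        "sigma": plant.sigma,
        "planted_date": FIXTURE_DATES[0],
        "n_sites": int(len(pooled)),
        "n_trap_samples": int(len(traps)),
        "seed": seed,
    }
    (out / "ground_truth.json").write_text(json.dumps(truth, indent=2))
    return truth


# ---------------------------------------------------------------------------
# full run

def run_all(config: RunConfig) -> Path:
    """Execute the whole analysis; returns the run directory.

    Stages: load scenes and sites -> compute indices per date -> extract the
    buffer-mean cube -> per stratum: CSR quadrat test, inter-index
    pre-screen, correlation scan (+ heatmaps), variance profiles, VIF +
    stepwise models.  Any stage failure aborts with the stage named; partial
    outputs stay on disk next to a FAILED marker.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "setup"
    try:
        stage = "load"
        scenes: dict[str, RasterScene] = {
            date: read_scene(path, date=date) for date, path in sorted(config.rasters.items())
        }
        if not scenes:
            raise ValueError("config lists no rasters")
        sites = read_sites(config.sites, column_map=config.site_columns or None)
        if "abundance" not in sites.columns:
            raise ValueError("site table has no abundance column")
        log.info("loaded %d sites, %d scenes", len(sites), len(scenes))

        stage = "indices"
        grids = {
            date: {name: compute_index(scene, name) for name in config.indices}
            for date, scene in scenes.items()
        }

        stage = "extract"
        scales = scale_grid_from_config(config)
        cube = extract_cube(
            grids, sites, scales, rule=config.extraction_rule, allow_edge=config.allow_edge
        )
        write_cube(out / "cube.csv", cube)
        log.info("extracted %d cube cells", len(cube))

        strata = list(dict.fromkeys(sites["stratum"]))
        csr_rows, model_rows = [], []
        for stratum in strata:
            sub = sites[sites["stratum"] == stratum]
            sdir = out / stratum
            sdir.mkdir(exist_ok=True)
            if len(sub) < 3:
                log.warning("stratum %s has %d sites (<3): skipped", stratum, len(sub))
                continue

            stage = f"csr-test[{stratum}]"
            res = quadrat_test(
                sub[["x", "y"]].to_numpy(), nx=config.quadrat_nx, ny=config.quadrat_ny
            )
            csr_rows.append(
                {
                    "stratum": stratum, "n_sites": len(sub), "chi2": res.statistic,
                    "df": res.df, "p": res.p, "random": res.p > config.alpha,
                }
            )

            stage = f"prescreen[{stratum}]"
            sub_cube = cube[cube["site_id"].isin(sub["site_id"])]
            pre = prescreen_indices(
                sub_cube,
                reference=config.prescreen_reference,
                threshold=config.prescreen_threshold,
                keep=config.prescreen_keep,
            )
            pd.DataFrame(
                {
                    "index": list(dict.fromkeys(cube["index"])),
                }
            ).assign(
                retained=lambda d: d["index"].isin(pre.retained),
                dropped=lambda d: d["index"].isin(pre.dropped),
                keep_flagged=lambda d: d["index"].isin(pre.kept_flagged),
            ).to_csv(sdir / "prescreen.csv", index=False)
            for date, cmat in pre.corr.items():
                cmat.to_csv(sdir / f"prescreen_corr_{date}.csv")

            stage = f"scan[{stratum}]"
            retained_cube = sub_cube[sub_cube["index"].isin(pre.retained)]
            scan = correlation_scan(retained_cube, sites, stratum, alpha=config.alpha)
            scan.to_csv(sdir / "scan.csv", index=False)
            prof = variance_profile(retained_cube, sites, stratum)
            prof.to_csv(sdir / "variance_profiles.csv", index=False)
            if config.make_figures:
                from .plotting import scan_heatmap, variance_profile_plot

                for name in pre.retained:
                    scan_heatmap(scan, name, out=sdir / f"heatmap_{name}.png", alpha=config.alpha)
                variance_profile_plot(prof, out=sdir / "variance_profiles.png")

            stage = f"model[{stratum}]"
            reports = per_scale_models(
                retained_cube, sites, stratum, scan=scan,
                vif_threshold=config.vif_threshold,
                direction=config.stepwise_direction,
                criterion=config.stepwise_criterion,
            )
            frame = pd.concat([r.to_frame() for r in reports], ignore_index=True)
            frame.to_csv(sdir / "models.csv", index=False)
            model_rows.append(frame)

        stage = "summarise"
        pd.DataFrame(csr_rows).to_csv(out / "csr_test.csv", index=False)
        if model_rows:
            pd.concat(model_rows, ignore_index=True).to_csv(out / "models.csv", index=False)
        manifest = {
            "package": "steppescan",
            "version": __version__,
            "seed": config.seed,
            "config_hash": config.config_hash(),
            "config": {k: list(v) if isinstance(v, tuple) else v for k, v in config.__dict__.items()},
            "n_sites": int(len(sites)),
            "n_cube_cells": int(len(cube)),
            "strata": strata,
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    except Exception:
        (out / "FAILED").write_text(f"stage: {stage}\n")
        log.exception("pipeline failed at stage %s", stage)
        raise
    return out
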