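"""End-to-end orchestration: scenario -> met -> dispersion -> chemistry ->
exposure -> health -> equity.

Two entry points:

* :func:`analyze_scenario` — in-memory pipeline over already-built region
  and met objects; returns a dict of result frames. This is the fast path
  used programmatically.
* :func:`run_pipeline` — file-based orchestration driven by a
  :class:`RunConfig`: each stage reads its inputs from, and writes its
  outputs to, the run directory, so the chained CLI subcommands and
  ``run-all`` produce byte-identical payloads.

A single global seed fans out to per-stage seeds through
``numpy.random.SeedSequence(seed).spawn``: child 0 drives the region
generator, child 1 spawns one grandchild per met year, child 2 seeds the
equity permutation tests. Stages are therefore independently reproducible.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .region import (GradientSpec, PointSourceSpec, generate_region,
                     read_scenario, write_scenario)
from .met import WindroseSpec, generate_met_year, read_met_csv, write_met_csv
from .dispersion import simulate_hourly_field
from .chemistry import ChemistryConfig, convert_nox_to_no2
from .exposure import (DEFAULT_BASIS, cer, max_min_ratio, summarize_exposure,
                       write_exposure_csv)
from .health import ASTHMA_CRF, MORTALITY_CRF, burden_table
from .equity import (intersectional_groups, quintile_table, regression_table,
                     stratify_by_poc)

FLOAT_FMT = "%.10g"

#: files a completed run directory contains (besides the manifest)
RUN_FILES = (
    "blockgroups.geojson", "blockgroups.csv", "scenario.yaml", "met.csv",
    "hourly_no2.csv", "exposure_summary.csv", "burden_mortality.csv",
    "burden_asthma.csv", "equity_quintiles.csv", "equity_poc_strata.csv",
    "equity_intersectional.csv", "equity_regressions.csv",
)


@dataclass
class RunConfig:
    """Validated run configuration (YAML-serializable)."""

    n_blockgroups: int = 200
    radius_km: float = 50.0
    min_distance_km: float = 2.0
    gradient: dict = field(default_factory=dict)     # GradientSpec kwargs
    source: dict = field(default_factory=dict)       # PointSourceSpec overrides
    ozone_background: float = 36.8
    met_years: list = field(default_factory=lambda: [2022])
    windrose: dict = field(default_factory=dict)     # WindroseSpec kwargs
    chemistry: dict = field(default_factory=dict)    # ChemistryConfig kwargs
    equity_k: int = 8
    permutations: int = 999
    seed: int = 0
    output_dir: str = "run_output"

    def __post_init__(self):
        if self.n_blockgroups < 5:
            raise ValueError("n_blockgroups must be >= 5")
        if not self.met_years:
            raise ValueError("met_years must be non-empty")
        # construct eagerly so malformed sections fail at validation time
        self.gradient_spec()
        self.windrose_spec()
        self.chemistry_config()

    def gradient_spec(self) -> GradientSpec:
        return GradientSpec(**self.gradient)

    def windrose_spec(self) -> WindroseSpec:
        kw = dict(self.windrose)
        if "sector_probs" in kw:
            kw["sector_probs"] = tuple(kw["sector_probs"])
        return WindroseSpec(**kw)

    def chemistry_config(self) -> ChemistryConfig:
        kw = {"ozone_background": self.ozone_background, **self.chemistry}
        return ChemistryConfig(**kw)

    def stage_seeds(self) -> dict:
        ss = np.random.SeedSequence(self.seed)
        region_ss, met_ss, equity_ss = ss.spawn(3)
        met_children = met_ss.spawn(len(self.met_years))
        to_int = lambda s: int(s.generate_state(1)[0] % (2 ** 31))
        return {
            "region": to_int(region_ss),
            "met": {int(y): to_int(c) for y, c in zip(self.met_years, met_children)},
            "equity": to_int(equity_ss),
        }

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def config_hash(self) -> str:
        payload = yaml.safe_dump(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


# ---------------------------------------------------------------------------
# in-memory pipeline

def analyze_scenario(scenario, met: pd.DataFrame,
                     chem_cfg: ChemistryConfig | None = None,
                     equity_k: int = 8, equity_seed: int = 0,
                     basis: str = DEFAULT_BASIS) -> dict:
    """Run dispersion through equity on in-memory objects.

    Returns a dict with the hourly NO2 field, exposure summary, burden
    tables, CER, max/min ratio, quintile table, POC strata, intersectional
    groups, and regression results.
    """
    if chem_cfg is None:
        chem_cfg = ChemistryConfig(ozone_background=scenario.ozone_background)
    hourly_nox = simulate_hourly_field(scenario.source, scenario, met)
    hourly_no2 = convert_nox_to_no2(hourly_nox.to_numpy(), chem_cfg)
    hourly_no2 = pd.DataFrame(hourly_no2, index=hourly_nox.index,
                              columns=hourly_nox.columns)
    hourly_no2.attrs.update(hourly_nox.attrs)
    summaries = summarize_exposure(hourly_no2)
    exposure = summaries[basis]
    mort = burden_table(MORTALITY_CRF, exposure, scenario.block_groups)
    asthma = burden_table(ASTHMA_CRF, exposure, scenario.block_groups)
    qtable = quintile_table(scenario.block_groups, exposure,
                            mortality_rate=mort["rate_per_100k"],
                            asthma_rate=asthma["rate_per_100k"])
    strata = stratify_by_poc(scenario.block_groups, mort["rate_per_100k"])
    inter = intersectional_groups(scenario.block_groups, exposure)
    reg_results, reg_frame = regression_table(scenario.block_groups, exposure,
                                              k=equity_k, seed=equity_seed)
    return {
        "hourly_no2": hourly_no2,
        "exposure_summary": summaries,
        "cer": cer(summaries, scenario.source.annual_emissions, basis=basis),
        "max_min_ratio": max_min_ratio(summaries, basis=basis),
        "burden_mortality": mort,
        "burden_asthma": asthma,
        "quintile_table": qtable,
        "poc_strata": strata,
        "intersectional": inter,
        "regressions": reg_results,
        "regression_frame": reg_frame,
        "calm_fraction": hourly_no2.attrs.get("calm_fraction", float("nan")),
    }


# ---------------------------------------------------------------------------
# file-based stages

def _p(run_dir, name) -> Path:
    return Path(run_dir) / name


def stage_simulate_region(config: RunConfig, run_dir) -> None:
    seeds = config.stage_seeds()
    source = None
    if config.source:
        source = PointSourceSpec(**{
            "source_id": "S1", "x": 0.0, "y": 0.0, "stack_height": 40.0,
            "stack_diameter": 3.0, "exit_velocity": 20.0,
            "exit_temperature": 450.0, "annual_emissions": 4267.0,
            **config.source})
    scenario = generate_region(
        config.n_blockgroups, radius_km=config.radius_km,
        gradient_spec=config.gradient_spec(), seed=seeds["region"],
        source=source, ozone_background=config.ozone_background,
        min_distance_km=config.min_distance_km)
    write_scenario(scenario, _p(run_dir, "blockgroups.geojson"),
                   _p(run_dir, "blockgroups.csv"), _p(run_dir, "scenario.yaml"))


def stage_simulate_met(config: RunConfig, run_dir) -> None:
    seeds = config.stage_seeds()
    frames = [generate_met_year(int(y), config.windrose_spec(),
                                seed=seeds["met"][int(y)])
              for y in config.met_years]
    write_met_csv(pd.concat(frames), _p(run_dir, "met.csv"))


def stage_disperse(config: RunConfig, run_dir) -> None:
    """Dispersion + chemistry: hourly NO2 ppb, long-format CSV."""
    scenario = read_scenario(_p(run_dir, "blockgroups.geojson"),
                             _p(run_dir, "scenario.yaml"))
    met = read_met_csv(_p(run_dir, "met.csv"))
    hourly_nox = simulate_hourly_field(scenario.source, scenario, met)
    cfg = config.chemistry_config()
    no2 = pd.DataFrame(convert_nox_to_no2(hourly_nox.to_numpy(), cfg),
                       index=hourly_nox.index, columns=hourly_nox.columns)
    long = no2.stack(future_stack=True).rename("no2_ppb").reset_index()
    long.columns = ["timestamp", "bg_id", "no2_ppb"]
    long.to_csv(_p(run_dir, "hourly_no2.csv"), index=False,
                float_format="%.6g", date_format="%Y-%m-%dT%H:%M:%S")
    _p(run_dir, "calm_fraction.json").write_text(json.dumps(
        {"calm_fraction": hourly_nox.attrs["calm_fraction"],
         "scheme": cfg.scheme}))


def _read_hourly(run_dir) -> pd.DataFrame:
    long = pd.read_csv(_p(run_dir, "hourly_no2.csv"), parse_dates=["timestamp"])
    return long.pivot(index="timestamp", columns="bg_id", values="no2_ppb")


def stage_expose(config: RunConfig, run_dir) -> None:
    summaries = summarize_exposure(_read_hourly(run_dir))
    write_exposure_csv(summaries, _p(run_dir, "exposure_summary.csv"))


def stage_health(config: RunConfig, run_dir) -> None:
    scenario = read_scenario(_p(run_dir, "blockgroups.geojson"),
                             _p(run_dir, "scenario.yaml"))
    summaries = pd.read_csv(_p(run_dir, "exposure_summary.csv"),
                            index_col="bg_id")
    exposure = summaries[DEFAULT_BASIS]
    for crf, name in ((MORTALITY_CRF, "burden_mortality.csv"),
                      (ASTHMA_CRF, "burden_asthma.csv")):
        tbl = burden_table(crf, exposure, scenario.block_groups)
        tbl.to_csv(_p(run_dir, name), float_format=FLOAT_FMT)


def stage_equity(config: RunConfig, run_dir) -> None:
    seeds = config.stage_seeds()
    scenario = read_scenario(_p(run_dir, "blockgroups.geojson"),
                             _p(run_dir, "scenario.yaml"))
    summaries = pd.read_csv(_p(run_dir, "exposure_summary.csv"),
                            index_col="bg_id")
    exposure = summaries[DEFAULT_BASIS]
    mort = pd.read_csv(_p(run_dir, "burden_mortality.csv"), index_col="bg_id")
    asthma = pd.read_csv(_p(run_dir, "burden_asthma.csv"), index_col="bg_id")
    qtable = quintile_table(scenario.block_groups, exposure,
                            mortality_rate=mort["rate_per_100k"],
                            asthma_rate=asthma["rate_per_100k"])
    qtable.to_csv(_p(run_dir, "equity_quintiles.csv"), index=False,
                  float_format=FLOAT_FMT)
    strata = stratify_by_poc(scenario.block_groups, mort["rate_per_100k"])
    strata.to_csv(_p(run_dir, "equity_poc_strata.csv"), index=False,
                  float_format=FLOAT_FMT)
    inter = intersectional_groups(scenario.block_groups, exposure)
    inter.to_csv(_p(run_dir, "equity_intersectional.csv"), index=False,
                 float_format=FLOAT_FMT)
    _, reg_frame = regression_table(scenario.block_groups, exposure,
                                    k=config.equity_k, seed=seeds["equity"])
    reg_frame.to_csv(_p(run_dir, "equity_regressions.csv"), index=False,
                     float_format=FLOAT_FMT)


STAGES = (
    ("simulate-region", stage_simulate_region),
    ("simulate-met", stage_simulate_met),
    ("disperse", stage_disperse),
    ("expose", stage_expose),
    ("health", stage_health),
    ("equity", stage_equity),
)


def run_pipeline(config: RunConfig, run_dir=None) -> Path:
    """Execute every stage in order; returns the run directory.

    Writes a ``manifest.json`` recording package version, seed, config
    hash, per-stage wall time, calm-hour fraction and row counts. Reruns
    with the same config are byte-identical for all CSV payloads.
    """
    run_dir = Path(run_dir if run_dir is not None else config.output_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    timings = {}
    for name, fn in STAGES:
        t0 = time.perf_counter()
        try:
            fn(config, run_dir)
        except Exception as exc:  # surface the failing stage by name
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        timings[name] = round(time.perf_counter() - t0, 3)

    calm = json.loads(_p(run_dir, "calm_fraction.json").read_text())
    counts = {
        "block_groups": int(len(pd.read_csv(_p(run_dir, "blockgroups.csv")))),
        "met_hours": int(len(pd.read_csv(_p(run_dir, "met.csv")))),
        "hourly_records": int(len(pd.read_csv(_p(run_dir, "hourly_no2.csv")))),
    }
    manifest = {
        "package": "nearsource",
        "version": __version__,
        "versions": {"numpy": np.__version__, "pandas": pd.__version__},
        "seed": config.seed,
        "stage_seeds": config.stage_seeds(),
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "calm_fraction": calm["calm_fraction"],
        "chemistry_scheme": calm["scheme"],
        "counts": counts,
        "outputs": list(RUN_FILES),
        "timings_s": timings,
        "created": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    _p(run_dir, "manifest.json").write_text(json.dumps(manifest, indent=1))
    return run_dir
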