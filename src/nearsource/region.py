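"""Synthetic study region: a point source surrounded by census-style block
groups with demographics, baseline rates, and controllable planted spatial
structure.

The generator stands in for the real inputs of a near-source assessment
(facility emission inventory, ACS/EJScreen demographics, small-area baseline
mortality, GBD asthma incidence). Its purpose is to plant *known* spatial
associations — e.g. a negative correlation between the share of people of
color and distance from the source — so the equity and health stages can be
validated against ground truth.

Coordinates are a local planar frame in meters centered on the source
(azimuthal-equidistant for practical purposes); at a 50 km radius the
planar approximation is far below any resolution that matters here.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .units import emission_rate_gps  # noqa: F401  (re-exported: the emitter's rate op)

#: age bins; the first bin (0-14) carries the pediatric asthma endpoint,
#: bins from 65-74 up define the elderly share.
AGE_BINS = ("0-14", "15-24", "25-34", "35-44", "45-54", "55-64",
            "65-74", "75-84", "85+")

#: national-like age composition (fractions, sum 1)
DEFAULT_AGE_SHARES = (0.18, 0.13, 0.14, 0.13, 0.12, 0.13, 0.10, 0.05, 0.02)

#: national-like all-cause mortality, deaths per 100,000 per year per bin
DEFAULT_MORTALITY_PER_100K = (30.0, 80.0, 130.0, 200.0, 400.0, 900.0,
                              1800.0, 4500.0, 13000.0)

#: pediatric (0-14) asthma incidence, cases per 100,000 children per year
DEFAULT_ASTHMA_INCIDENCE_PER_100K = 1400.0


@dataclass(frozen=True)
class PointSourceSpec:
    """A high-emitting stack treated as a single point source."""

    source_id: str
    x: float
    y: float
    stack_height: float          # m
    stack_diameter: float        # m
    exit_velocity: float         # m/s
    exit_temperature: float      # K
    annual_emissions: float      # NOx short tons/yr
    in_stack_no2_fraction: float = 0.10

    def __post_init__(self):
        if self.stack_height <= 0:
            raise ValueError("stack_height must be > 0")
        if self.exit_velocity < 0:
            raise ValueError("exit_velocity must be >= 0")
        if self.annual_emissions < 0:
            raise ValueError("annual_emissions must be >= 0")
        if not 0.0 <= self.in_stack_no2_fraction <= 1.0:
            raise ValueError("in_stack_no2_fraction must be in [0, 1]")

    @property
    def emission_rate_gps(self) -> float:
        """Constant emission rate in g/s implied by the annual total."""
        return emission_rate_gps(self.annual_emissions)


@dataclass(frozen=True)
class BlockGroup:
    """Receptor centroid plus the demographics the burden/equity stages use."""

    bg_id: str
    centroid_x: float
    centroid_y: float
    distance_km: float
    pop_by_age: tuple            # counts per AGE_BINS entry
    poc_frac: float              # share not identifying as non-Hispanic White
    li_frac: float               # share at <= 2x the federal poverty level
    baseline_mortality_by_age: tuple   # deaths per 100k/yr per AGE_BINS entry
    asthma_incidence_0_14: float       # cases per 100k children/yr

    def __post_init__(self):
        if len(self.pop_by_age) != len(AGE_BINS):
            raise ValueError("pop_by_age must have one entry per age bin")
        if len(self.baseline_mortality_by_age) != len(AGE_BINS):
            raise ValueError("baseline_mortality_by_age must match age bins")
        if any(p < 0 for p in self.pop_by_age):
            raise ValueError("populations must be >= 0")
        if not (0 <= self.poc_frac <= 1 and 0 <= self.li_frac <= 1):
            raise ValueError("poc_frac/li_frac must be in [0, 1]")
        if any(r < 0 for r in self.baseline_mortality_by_age) or self.asthma_incidence_0_14 < 0:
            raise ValueError("rates must be >= 0")

    @property
    def total_pop(self) -> float:
        return float(sum(self.pop_by_age))

    @property
    def elderly_frac(self) -> float:
        """Share of population aged 65 or older."""
        tot = self.total_pop
        if tot == 0:
            return 0.0
        return float(sum(self.pop_by_age[6:])) / tot


@dataclass(frozen=True)
class GradientSpec:
    """Planted associations between demographics and distance.

    ``r_poc_dist`` / ``r_li_dist`` are target Pearson correlations between
    the demographic fraction and centroid distance (negative values plant
    near-source clustering of the group). ``r_poc_li`` couples the two
    latent fields.
    """

    r_poc_dist: float = 0.0
    r_li_dist: float = 0.0
    r_poc_li: float = 0.5
    poc_mean: float = 0.40
    li_mean: float = 0.35
    logit_sd: float = 1.0

    def __post_init__(self):
        for name in ("r_poc_dist", "r_li_dist", "r_poc_li"):
            v = getattr(self, name)
            if not -1.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a correlation in [-1, 1], got {v}")


@dataclass
class RegionScenario:
    """A fully specified synthetic study region."""

    source: PointSourceSpec
    block_groups: list
    ozone_background: float      # ppb, annual arithmetic mean
    gradient_spec: GradientSpec = field(default_factory=GradientSpec)
    seed: int = 0
    radius_km: float = 50.0

    def to_frame(self) -> pd.DataFrame:
        """Block groups as a tidy DataFrame (one row per block group)."""
        rows = []
        for bg in self.block_groups:
            row = {
                "bg_id": bg.bg_id,
                "centroid_x": bg.centroid_x,
                "centroid_y": bg.centroid_y,
                "distance_km": bg.distance_km,
                "poc_frac": bg.poc_frac,
                "li_frac": bg.li_frac,
                "elderly_frac": bg.elderly_frac,
                "total_pop": bg.total_pop,
                "asthma_incidence_0_14": bg.asthma_incidence_0_14,
            }
            for b, p, m in zip(AGE_BINS, bg.pop_by_age, bg.baseline_mortality_by_age):
                row[f"pop_{b}"] = p
                row[f"mort_{b}"] = m
            rows.append(row)
        return pd.DataFrame(rows)


def _logistic(z):
    return 1.0 / (1.0 + np.exp(-z))


def _logit(p):
    return np.log(p / (1.0 - p))


def generate_region(n_blockgroups: int,
                    radius_km: float = 50.0,
                    gradient_spec: GradientSpec | None = None,
                    seed: int = 0,
                    source: PointSourceSpec | None = None,
                    ozone_background: float = 36.8,
                    min_distance_km: float = 2.0,
                    mean_pop: float = 1400.0) -> RegionScenario:
    """Generate a seeded synthetic study region.

    Centroids are drawn area-uniform over the annulus between
    ``min_distance_km`` and ``radius_km`` (the steady-state plume is
    undefined at the source itself, and real block-group centroids start a
    few km out). Demographic fractions are logistic transforms of Gaussian
    latent fields with the planted distance correlations of
    ``gradient_spec``; age structure and baseline mortality follow
    national-like defaults with multiplicative block-group noise.

    The output is fully determined by ``seed``.
    """
    if n_blockgroups < 5:
        raise ValueError("n_blockgroups must be >= 5")
    if radius_km <= 0:
        raise ValueError("radius_km must be > 0")
    if not 0 <= min_distance_km < radius_km:
        raise ValueError("min_distance_km must be in [0, radius_km)")
    gradient_spec = gradient_spec or GradientSpec()

    rng = np.random.default_rng(seed)
    n = n_blockgroups

    if source is None:
        source = PointSourceSpec(
            source_id="S1", x=0.0, y=0.0, stack_height=40.0,
            stack_diameter=3.0, exit_velocity=20.0, exit_temperature=450.0,
            annual_emissions=4267.0)

    # area-uniform radii over the annulus, uniform bearings
    u = rng.uniform(size=n)
    r_km = np.sqrt(min_distance_km**2 + u * (radius_km**2 - min_distance_km**2))
    theta = rng.uniform(0, 2 * np.pi, size=n)
    cx = source.x + r_km * 1000.0 * np.sin(theta)
    cy = source.y + r_km * 1000.0 * np.cos(theta)

    # latent Gaussian fields with planted distance correlation
    d_std = (r_km - r_km.mean()) / r_km.std()
    gs = gradient_spec
    eps_shared = rng.standard_normal(n)
    eps_poc = rng.standard_normal(n)
    eps_li = rng.standard_normal(n)
    c = np.sqrt(max(gs.r_poc_li, 0.0))
    noise_poc = c * eps_shared + np.sqrt(1 - c**2) * eps_poc
    noise_li = c * eps_shared + np.sqrt(1 - c**2) * eps_li
    z_poc = gs.r_poc_dist * d_std + np.sqrt(1 - gs.r_poc_dist**2) * noise_poc
    z_li = gs.r_li_dist * d_std + np.sqrt(1 - gs.r_li_dist**2) * noise_li
    poc = _logistic(_logit(gs.poc_mean) + gs.logit_sd * z_poc)
    li = _logistic(_logit(gs.li_mean) + gs.logit_sd * z_li)

    # populations and age structure: Dirichlet jitter around national shares
    total_pop = rng.lognormal(mean=np.log(mean_pop), sigma=0.4, size=n)
    shares = rng.dirichlet(np.asarray(DEFAULT_AGE_SHARES) * 120.0, size=n)
    pops = np.round(shares * total_pop[:, None]).astype(int)

    # baseline rates: multiplicative lognormal noise per block group
    mort_noise = rng.lognormal(mean=0.0, sigma=0.15, size=(n, len(AGE_BINS)))
    mort = np.asarray(DEFAULT_MORTALITY_PER_100K) * mort_noise
    asthma = DEFAULT_ASTHMA_INCIDENCE_PER_100K * rng.lognormal(0.0, 0.2, size=n)

    order = np.argsort(r_km, kind="stable")
    bgs = []
    for rank, i in enumerate(order):
        bgs.append(BlockGroup(
            bg_id=f"BG{rank:04d}",
            centroid_x=float(cx[i]), centroid_y=float(cy[i]),
            distance_km=float(r_km[i]),
            pop_by_age=tuple(int(v) for v in pops[i]),
            poc_frac=float(poc[i]), li_frac=float(li[i]),
            baseline_mortality_by_age=tuple(float(v) for v in mort[i]),
            asthma_incidence_0_14=float(asthma[i]),
        ))

    return RegionScenario(source=source, block_groups=bgs,
                          ozone_background=float(ozone_background),
                          gradient_spec=gradient_spec, seed=seed,
                          radius_km=float(radius_km))


# ---------------------------------------------------------------------------
# serialization

def blockgroups_to_geojson(scenario: RegionScenario) -> dict:
    """Block groups as a GeoJSON FeatureCollection of point features."""
    feats = []
    for bg in scenario.block_groups:
        props = {
            "bg_id": bg.bg_id, "distance_km": bg.distance_km,
            "poc_frac": bg.poc_frac, "li_frac": bg.li_frac,
            "elderly_frac": bg.elderly_frac,
            "pop_by_age": list(bg.pop_by_age),
            "baseline_mortality_by_age": list(bg.baseline_mortality_by_age),
            "asthma_incidence_0_14": bg.asthma_incidence_0_14,
        }
        feats.append({
            "type": "Feature",
            "geometry": {"type": "Point",
                         "coordinates": [bg.centroid_x, bg.centroid_y]},
            "properties": props,
        })
    return {"type": "FeatureCollection",
            "crs_note": "local planar meters centered on source",
            "features": feats}


def write_scenario(scenario: RegionScenario, bg_geojson_path, bg_csv_path,
                   source_yaml_path) -> None:
    """Write a scenario to disk: GeoJSON + CSV block groups, YAML source."""
    with open(bg_geojson_path, "w") as fh:
        json.dump(blockgroups_to_geojson(scenario), fh, indent=1)
    scenario.to_frame().to_csv(bg_csv_path, index=False, float_format="%.10g")
    meta = {
        "source": asdict(scenario.source),
        "ozone_background_ppb": scenario.ozone_background,
        "radius_km": scenario.radius_km,
        "seed": scenario.seed,
        "gradient_spec": asdict(scenario.gradient_spec),
    }
    with open(source_yaml_path, "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=True)


def read_scenario(bg_geojson_path, source_yaml_path) -> RegionScenario:
    """Rebuild a scenario from the GeoJSON + YAML pair written above."""
    with open(source_yaml_path) as fh:
        meta = yaml.safe_load(fh)
    source = PointSourceSpec(**meta["source"])
    with open(bg_geojson_path) as fh:
        gj = json.load(fh)
    bgs = []
    for feat in gj["features"]:
        p = feat["properties"]
        x, y = feat["geometry"]["coordinates"]
        bgs.append(BlockGroup(
            bg_id=p["bg_id"], centroid_x=x, centroid_y=y,
            distance_km=p["distance_km"],
            pop_by_age=tuple(p["pop_by_age"]),
            poc_frac=p["poc_frac"], li_frac=p["li_frac"],
            baseline_mortality_by_age=tuple(p["baseline_mortality_by_age"]),
            asthma_incidence_0_14=p["asthma_incidence_0_14"]))
    return RegionScenario(source=source, block_groups=bgs,
                          ozone_background=meta["ozone_background_ppb"],
                          gradient_spec=GradientSpec(**meta["gradient_spec"]),
                          seed=meta["seed"], radius_km=meta["radius_km"])
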