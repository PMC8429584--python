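"""Self-contained synthetic worlds for testing and demonstration.

`generate_world` builds a deterministic set of regions with the statistical
structure the pipeline assumes — sinusoidal 12-month temperature cycles per
climate archetype, lognormal monthly precipitation, latitude-driven day
length, clay and SOC stocks in configurable ranges, per-region feasible
class subsets that always contain a potential-natural-vegetation candidate,
land-use shares on the simplex, contiguous pixel footprints and country
assignments. It emulates the *structure* of real territorial units, not
real-world geographic CF patterns.

`make_known_answer_region` is a synthetic oracle: a constant-climate region
whose classes are tuned so every transition curve is a pure exponential
with a requested rate and requested equilibria, making the characterization
factors known in closed form.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .environment import MonthlyClimate, SoilProfile, iom_from_soc
from .lu_taxonomy import (FertilizationScenario, LandUseClass,
                          LandUseRegistry, ManagementRegime, ResidueFate,
                          WaterRegime, build_default_registry,
                          load_crop_coefficients, residue_c_input)
from .rothc import RothCParams, co2_partition_ratio, temperature_modifier
from .world import Grid, Region

__all__ = ["WorldSpec", "World", "generate_world",
           "make_known_answer_region", "save_world", "load_world",
           "DEFAULT_WORLD_CLASSES"]

#: Default class subset for generated worlds: every flow-mapping bucket is
#: represented (urban, grassland, two forests, rice, cereals with both
#: residue fates, irrigated and rainfed annuals, both permanent regimes).
DEFAULT_WORLD_CLASSES = (
    "urban",
    "grassland",
    "forest_broadleaf_deciduous_cool_temperate_moist",
    "forest_needleleaf_evergreen_warm_temperate_dry",
    "crop_wheat_rainfed_left",
    "crop_wheat_rainfed_removed",
    "crop_maize_irrigated_left",
    "crop_rice_irrigated_left",
    "crop_soybean_rainfed_na",
    "crop_potato_irrigated_na",
    "crop_olive_rainfed_na",
    "crop_grape_irrigated_na",
)

_ARCHETYPES = {
    # tavg mean, seasonal amplitude, monthly precip base (mm), |lat| range,
    # productivity factor, mature forest C input (t C/ha/yr), grass C input
    "tropical": dict(tmean=26.0, tamp=2.0, pbase=160.0, lat=(0.0, 20.0),
                     yield_factor=1.0, forest_input=4.5, grass_input=3.2),
    "temperate": dict(tmean=12.0, tamp=9.0, pbase=75.0, lat=(30.0, 55.0),
                      yield_factor=1.1, forest_input=3.2, grass_input=2.8),
    "boreal": dict(tmean=3.0, tamp=14.0, pbase=55.0, lat=(55.0, 68.0),
                   yield_factor=0.7, forest_input=1.8, grass_input=1.8),
}


@dataclass(frozen=True)
class WorldSpec:
    """Parameters of a generated world."""

    n_regions: int = 25
    n_countries: int = 5
    seed: int = 0
    archetype_weights: tuple = (0.35, 0.45, 0.20)  # tropical/temperate/boreal
    clay_range: tuple = (5.0, 45.0)
    soc_range: tuple = (30.0, 120.0)
    feasibility_density: float = 0.6
    class_ids: tuple = DEFAULT_WORLD_CLASSES

    def __post_init__(self):
        if not self.n_regions >= self.n_countries >= 1:
            raise ValueError("need n_regions >= n_countries >= 1")
        if not (self.clay_range[0] < self.clay_range[1]
                and self.soc_range[0] < self.soc_range[1]):
            raise ValueError("value ranges must be non-degenerate")
        if not 0 < self.feasibility_density <= 1:
            raise ValueError("feasibility_density must lie in (0, 1]")


@dataclass
class World:
    """A synthetic study area: regions, the class registry in play and the
    raster grid the footprints live on."""

    regions: list
    registry: LandUseRegistry
    grid: Grid
    spec: WorldSpec | None = None

    def region(self, region_id: str) -> Region:
        for r in self.regions:
            if r.region_id == region_id:
                return r
        raise KeyError(region_id)


def _rng(seed: int, region_index: int, purpose: int) -> np.random.Generator:
    """One stream per (seed, region, purpose): adding regions never perturbs
    the draws of existing ones."""
    seq = np.random.SeedSequence(entropy=int(seed) & 0x7FFFFFFF,
                                 spawn_key=(region_index, purpose))
    return np.random.default_rng(seq)


def generate_world(spec: WorldSpec = WorldSpec(),
                   registry: LandUseRegistry | None = None) -> World:
    """Generate a deterministic synthetic world from a `WorldSpec`."""
    full = build_default_registry() if registry is None else registry
    sub = full.subset(spec.class_ids)
    coefs = load_crop_coefficients()
    arch_names = list(_ARCHETYPES)
    weights = np.asarray(spec.archetype_weights, dtype=float)
    weights = weights / weights.sum()
    n_block_cols = math.ceil(math.sqrt(spec.n_regions))
    n_block_rows = math.ceil(spec.n_regions / n_block_cols)
    grid = Grid(lat0=55.0, lon0=-30.0, n_rows=2 * n_block_rows,
                n_cols=2 * n_block_cols)
    months = np.arange(12)
    regions = []
    for i in range(spec.n_regions):
        rid = f"R{i:04d}"
        rng_clim = _rng(spec.seed, i, 0)
        rng_soil = _rng(spec.seed, i, 1)
        rng_feas = _rng(spec.seed, i, 2)
        rng_yield = _rng(spec.seed, i, 3)
        rng_share = _rng(spec.seed, i, 4)

        arch = _ARCHETYPES[arch_names[rng_clim.choice(3, p=weights)]]
        lat = float(rng_clim.uniform(*arch["lat"]))
        tmean = arch["tmean"] + rng_clim.normal(0.0, 1.5)
        tamp = arch["tamp"] * rng_clim.uniform(0.8, 1.2)
        tavg = tmean + tamp * np.sin(2 * np.pi * (months - 3.0) / 12.0)
        season = 1.0 + 0.4 * np.sin(2 * np.pi * (months - 5.0) / 12.0)
        precip = np.exp(rng_clim.normal(np.log(arch["pbase"] * season), 0.30))
        dl_amp = min(10.0, 12.0 * lat / 90.0 * 1.3)
        day_length = np.clip(12.0 + dl_amp
                             * np.sin(2 * np.pi * (months - 2.5) / 12.0),
                             0.0, 24.0)
        climate = MonthlyClimate(tavg=tavg, precip=precip,
                                 day_length=day_length)

        clay = float(rng_soil.uniform(*spec.clay_range))
        soc_init = float(rng_soil.uniform(*spec.soc_range))
        soil = SoilProfile(clay=clay, soc_init=soc_init,
                           iom=float(iom_from_soc(soc_init)))

        feasible = ["urban"]
        natural = [cid for cid in sub.class_ids
                   if sub[cid].category in ("forest", "grassland")]
        for cid in natural:
            p = 0.85 if sub[cid].category == "grassland" else 0.5
            if rng_feas.random() < p:
                feasible.append(cid)
        if len(feasible) == 1:  # guarantee a PNV candidate
            feasible.append("grassland" if "grassland" in sub.class_ids
                            else natural[0])
        crops = [cid for cid in sub.class_ids
                 if sub[cid].category == "cropland"]
        picked = [cid for cid in crops
                  if rng_feas.random() < spec.feasibility_density]
        if crops and not picked:
            picked = [crops[0]]
        feasible.extend(picked)
        feasible = sorted(set(feasible))

        c_inputs = {}
        for cid in feasible:
            cls = sub[cid]
            if cls.category == "urban":
                continue
            if cls.category == "forest":
                c_inputs[cid] = arch["forest_input"] * float(
                    rng_yield.lognormal(0.0, 0.15))
            elif cls.category == "grassland":
                c_inputs[cid] = arch["grass_input"] * float(
                    rng_yield.lognormal(0.0, 0.15))
            else:
                row = coefs.loc[cls.crop_name]
                yld = float(row["base_yield"]) * arch["yield_factor"] * float(
                    rng_yield.lognormal(0.0, 0.20))
                removed = 1.0 if (cls.management.residue_fate
                                  is ResidueFate.REMOVED) else 0.0
                if cls.management.water_regime is WaterRegime.IRRIGATED:
                    yld *= 1.25
                c_inputs[cid] = residue_c_input(
                    yld, dict(slope=row["slope"], intercept=row["intercept"],
                              root_shoot_ratio=row["root_shoot_ratio"],
                              c_fraction=row["c_fraction"],
                              residue_removed_fraction=removed))

        raw = rng_share.dirichlet([3.0, 2.0, 2.0, 0.4])
        scale = rng_share.uniform(0.75, 1.0)
        shares = dict(zip(("cropland", "forestry", "grazing", "urban"),
                          (raw * scale).tolist()))

        br, bc = divmod(i, n_block_cols)
        footprint = (2 * br, 2 * bc, 2, 2)
        area = 4 * 8540.0 * math.cos(math.radians(lat))
        country = f"C{i * spec.n_countries // spec.n_regions:02d}"
        regions.append(Region(region_id=rid, country=country, area_ha=area,
                              climate=climate, soil=soil,
                              feasible_classes=tuple(feasible),
                              lu_shares=shares, c_inputs=c_inputs, lat=lat,
                              lon=grid.lon0 + 2 * bc * grid.pixel_size,
                              footprint=footprint))
    return World(regions=regions, registry=sub, grid=grid, spec=spec)


# ---------------------------------------------------------------------------
# Known-answer oracle region

def make_known_answer_region(asoc_pnv: float = 100.0, asoc_lu: float = 60.0,
                             k: float = 0.05, iom: float = 2.0,
                             clay: float = 20.0):
    """Synthetic constant-climate region whose two classes have forced
    equilibria and a forced pure-exponential regeneration rate.

    Setting all four decay constants equal makes the total active stock
    decay geometrically with one rate regardless of how carbon is spread
    over the pools, so every transition curve is exactly
    ``asoc − D·exp(−k t)`` on the monthly grid. The common decay constant is
    solved so the effective annual rate equals ``k``, and the constant
    monthly inputs are chosen so the equilibria hit the requested stocks
    exactly. Closed forms: occupation CF = asoc_pnv − asoc_lu; CF of
    transforming PNV into the class = (asoc_pnv − asoc_lu)/k.

    Returns ``(region, registry, params)`` — run the pipeline with the
    returned `RothCParams`.
    """
    if not (asoc_pnv > iom and asoc_lu > iom):
        raise ValueError("target stocks must exceed the inert pool")
    if k <= 0:
        raise ValueError("target rate must be positive")
    x = co2_partition_ratio(clay)
    tavg = np.full(12, 15.0)
    climate = MonthlyClimate(tavg=tavg, precip=np.full(12, 200.0),
                             day_length=np.full(12, 12.0),
                             days_in_month=np.full(12, 30))
    abc = float(temperature_modifier(15.0)) * 1.0 * 0.6  # covered, wet soil

    def k_eff(k0):
        kappa = k0 * abc / 12.0
        lam = math.exp(-kappa) + (1.0 - math.exp(-kappa)) / (1.0 + x)
        return -12.0 * math.log(lam)

    k_max = 12.0 * math.log(1.0 + x)
    if k >= k_eff(1e6) or k >= k_max:
        raise ValueError(f"target rate {k} is unreachable (max ~{k_max:.3g})")
    k0 = brentq(lambda z: k_eff(z) - k, 1e-9, 1e6, xtol=1e-13, rtol=1e-14)
    lam_month = math.exp(-k / 12.0)

    params = RothCParams(k_dpm=k0, k_rpm=k0, k_bio=k0, k_hum=k0)
    pnv_cls = LandUseClass(class_id="ka_pnv", category="grassland",
                           dpm_rpm_ratio=0.67, cover_calendar=(1,) * 12)
    lu_cls = LandUseClass(class_id="ka_crop", category="cropland",
                          crop_type="permanent", dpm_rpm_ratio=1.44,
                          cover_calendar=(1,) * 12,
                          management=ManagementRegime(
                              WaterRegime.RAINFED, ResidueFate.NOT_APPLICABLE,
                              FertilizationScenario.NONE))
    registry = LandUseRegistry([pnv_cls, lu_cls])
    c_inputs = {"ka_pnv": 12.0 * (asoc_pnv - iom) * (1.0 - lam_month),
                "ka_crop": 12.0 * (asoc_lu - iom) * (1.0 - lam_month)}
    soil = SoilProfile(clay=clay, soc_init=asoc_pnv, iom=iom)
    region = Region(region_id="KA", country="KA0", area_ha=1000.0,
                    climate=climate, soil=soil,
                    feasible_classes=("ka_crop", "ka_pnv"),
                    lu_shares=dict(cropland=0.5, grazing=0.5),
                    c_inputs=c_inputs, footprint=(0, 0, 1, 1))
    return region, registry, params


# ---------------------------------------------------------------------------
# World serialization (plain-text fixture bundle)

def save_world(world: World, directory) -> None:
    """Write a world to a directory of tidy CSVs plus a grid JSON."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    regions = world.regions
    pd.DataFrame([
        dict(region_id=r.region_id, country=r.country, area_ha=r.area_ha,
             clay=r.soil.clay, depth=r.soil.depth, soc_init=r.soil.soc_init,
             iom=r.soil.iom, lat=r.lat, lon=r.lon,
             row0=r.footprint[0], col0=r.footprint[1],
             fp_rows=r.footprint[2], fp_cols=r.footprint[3])
        for r in regions]).to_csv(d / "regions.csv", index=False)
    pd.DataFrame([
        dict(region_id=r.region_id, month=m + 1,
             tavg=r.climate.tavg[m], precip=r.climate.precip[m],
             day_length=r.climate.day_length[m],
             days=int(r.climate.days_in_month[m]))
        for r in regions for m in range(12)]).to_csv(d / "climate.csv",
                                                     index=False)
    pd.DataFrame([
        dict(region_id=r.region_id, **r.lu_shares) for r in regions
    ]).to_csv(d / "shares.csv", index=False)
    pd.DataFrame([
        dict(region_id=r.region_id, class_id=cid,
             annual_c_input=r.c_inputs.get(cid, 0.0))
        for r in regions for cid in r.feasible_classes
    ]).to_csv(d / "feasible.csv", index=False)
    with open(d / "grid.json", "w") as fh:
        json.dump(dict(lat0=world.grid.lat0, lon0=world.grid.lon0,
                       n_rows=world.grid.n_rows, n_cols=world.grid.n_cols,
                       pixel_size=world.grid.pixel_size,
                       class_ids=list(world.registry.class_ids)), fh, indent=1)


def load_world(directory) -> World:
    """Reload a world saved by `save_world`."""
    d = Path(directory)
    with open(d / "grid.json") as fh:
        meta = json.load(fh)
    grid = Grid(lat0=meta["lat0"], lon0=meta["lon0"], n_rows=meta["n_rows"],
                n_cols=meta["n_cols"], pixel_size=meta["pixel_size"])
    registry = build_default_registry().subset(meta["class_ids"])
    rdf = pd.read_csv(d / "regions.csv")
    cdf = pd.read_csv(d / "climate.csv").set_index(["region_id", "month"])
    sdf = pd.read_csv(d / "shares.csv").set_index("region_id")
    fdf = pd.read_csv(d / "feasible.csv")
    regions = []
    for _, row in rdf.iterrows():
        rid = row["region_id"]
        cm = cdf.loc[rid].sort_index()
        climate = MonthlyClimate(tavg=cm["tavg"].to_numpy(),
                                 precip=cm["precip"].to_numpy(),
                                 day_length=cm["day_length"].to_numpy(),
                                 days_in_month=cm["days"].to_numpy())
        soil = SoilProfile(clay=row["clay"], soc_init=row["soc_init"],
                           depth=row["depth"], iom=row["iom"])
        feas = fdf[fdf["region_id"] == rid]
        regions.append(Region(
            region_id=rid, country=row["country"], area_ha=row["area_ha"],
            climate=climate, soil=soil,
            feasible_classes=tuple(feas["class_id"]),
            lu_shares=sdf.loc[rid].to_dict(),
            c_inputs=dict(zip(feas["class_id"], feas["annual_c_input"])),
            lat=row["lat"], lon=row["lon"],
            footprint=(int(row["row0"]), int(row["col0"]),
                       int(row["fp_rows"]), int(row["fp_cols"]))))
    return World(regions=regions, registry=registry, grid=grid)
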