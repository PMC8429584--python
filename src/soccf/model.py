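"""Model / Results surface tying the pipeline together.

`SOCDepletionModel` is built from data — a set of regions and a land-use
class registry — plus the turnover parameters and an input-variability
configuration. Its `fit` runs the full characterization (deterministic, or
Monte Carlo over perturbed inputs when ``n_runs > 1``) and returns a
`SOCDepletionResults` holding per-region per-run attainable stocks and
regeneration impacts, from which CF tables, country aggregates,
elementary-flow tables, rasters, exchange bundles, plots and a text summary
are derived.

Example
-------
>>> from soccf import SOCDepletionModel
>>> from soccf.synthetic import WorldSpec
>>> model = SOCDepletionModel.from_world_spec(WorldSpec(n_regions=4, seed=1))
>>> res = model.fit(n_runs=10, seed=7)
>>> res.foreground_occupation().head()
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import aggregation, soc_curves
from .lu_taxonomy import LandUseRegistry, load_flow_mapping
from .rothc import DEFAULT_PARAMS, RothCParams
from .synthetic import World, WorldSpec, generate_world
from .uncertainty import PerturbationConfig, RegionMonteCarlo, monte_carlo_region

__all__ = ["SOCDepletionModel", "SOCDepletionResults"]


class SOCDepletionModel:
    """Process-based SOC-depletion characterization of a set of regions.

    Parameters
    ----------
    regions : sequence of `world.Region`
    registry : `lu_taxonomy.LandUseRegistry`
    params : `rothc.RothCParams`, optional
        Turnover constants (decay rates, partition coefficients ...).
    perturbation : `uncertainty.PerturbationConfig`, optional
        Intra-region input variability for Monte Carlo fits; the defaults
        are used when only ``n_runs``/``seed`` are passed to `fit`.
    grid : `world.Grid`, optional
        Raster grid for map export.
    growth_years : int
        Forest growth period simulated with ramped carbon inputs.
    """

    def __init__(self, regions, registry: LandUseRegistry,
                 params: RothCParams = DEFAULT_PARAMS,
                 perturbation: PerturbationConfig | None = None,
                 grid=None, growth_years: int = soc_curves.GROWTH_YEARS):
        self.regions = list(regions)
        self.registry = registry
        self.params = params
        self.perturbation = perturbation
        self.grid = grid
        self.growth_years = growth_years

    @classmethod
    def from_world(cls, world: World, **kwargs) -> "SOCDepletionModel":
        return cls(world.regions, world.registry, grid=world.grid, **kwargs)

    @classmethod
    def from_world_spec(cls, spec: WorldSpec = WorldSpec(),
                        **kwargs) -> "SOCDepletionModel":
        """Build the model on a generated synthetic world."""
        return cls.from_world(generate_world(spec), **kwargs)

    def fit(self, n_runs: int | None = None,
            seed: int | None = None) -> "SOCDepletionResults":
        """Run the characterization.

        With ``n_runs == 1`` (default when no perturbation config is set)
        the inputs are used as-is; otherwise each run perturbs every input
        family once per region and all factors in a run share the draw.
        """
        pert = self.perturbation
        if pert is None:
            pert = PerturbationConfig(n_runs=n_runs or 1, seed=seed or 0)
        else:
            changes = {}
            if n_runs is not None:
                changes["n_runs"] = n_runs
            if seed is not None:
                changes["seed"] = seed
            if changes:
                pert = PerturbationConfig(**{**pert.__dict__, **changes})
        if pert.n_runs == 1:
            pert = PerturbationConfig(tavg_sd=0, precip_cv=0, clay_cv=0,
                                      soc_init_cv=0, c_input_cv=0, n_runs=1,
                                      seed=pert.seed)
        import warnings as _warnings
        mc = {}
        for region in self.regions:
            with _warnings.catch_warnings():
                _warnings.simplefilter("ignore")
                mc[region.region_id] = monte_carlo_region(
                    region, self.registry, pert, self.params,
                    growth_years=self.growth_years)
        return SOCDepletionResults(self, mc, pert)

    def transition_curve(self, region_id: str, lu_from: str, lu_to: str):
        """Deterministic SOC transition curve for one region and class pair."""
        region = next(r for r in self.regions if r.region_id == region_id)
        return soc_curves.simulate_transition(
            region, lu_from, lu_to, self.registry, self.params,
            growth_years=self.growth_years)


class SOCDepletionResults:
    """Fitted characterization factors with their Monte Carlo spreads."""

    def __init__(self, model: SOCDepletionModel, mc_by_region: dict,
                 perturbation: PerturbationConfig):
        self.model = model
        self.mc_by_region: dict[str, RegionMonteCarlo] = mc_by_region
        self.perturbation = perturbation
        self.n_runs = perturbation.n_runs

    # -- per-region tables --------------------------------------------------

    def attainable_soc(self) -> pd.DataFrame:
        """Attainable SOC per (region, class): mean and spread over runs."""
        rows = []
        for rid, mc in self.mc_by_region.items():
            mean, sd = mc.stats(mc.asoc)
            for k, cid in enumerate(mc.class_ids):
                rows.append(dict(region_id=rid, class_id=cid,
                                 mean=float(mean[k]), stdev=float(sd[k]),
                                 units="t C/ha"))
        return pd.DataFrame(rows)

    def pnv(self) -> pd.DataFrame:
        """Modal PNV class per region (PNV is re-selected in every run)."""
        rows = []
        for rid, mc in self.mc_by_region.items():
            idx = np.bincount(mc.pnv_index).argmax()
            rows.append(dict(region_id=rid, pnv_class_id=mc.class_ids[idx],
                             asoc_pnv=float(mc.asoc[:, idx].mean())))
        return pd.DataFrame(rows)

    def foreground_occupation(self) -> pd.DataFrame:
        """Occupation CFs (t C/ha) per (region, class)."""
        rows = []
        for rid, mc in self.mc_by_region.items():
            mean, sd = mc.stats(mc.occupation_runs())
            for k, cid in enumerate(mc.class_ids):
                rows.append(dict(region_id=rid, flow_kind="occupation",
                                 lu2=cid, mean=float(mean[k]),
                                 stdev=float(sd[k]), units="t C/ha"))
        return pd.DataFrame(rows)

    def foreground_transformation(self) -> pd.DataFrame:
        """Transformation CFs (t C·yr/ha) per (region, ordered class pair).

        One record per unordered pair (lu1 < lu2); the reverse transition is
        the exact negative.
        """
        rows = []
        for rid, mc in self.mc_by_region.items():
            for i, lu1 in enumerate(mc.class_ids):
                for j in range(i + 1, len(mc.class_ids)):
                    runs = mc.transformation_runs(i, j)
                    sd = float(runs.std(ddof=1)) if len(runs) > 1 else 0.0
                    rows.append(dict(region_id=rid,
                                     flow_kind="transformation_foreground",
                                     lu1=lu1, lu2=mc.class_ids[j],
                                     mean=float(runs.mean()), stdev=sd,
                                     units="t C.yr/ha"))
        return pd.DataFrame(rows)

    def background_transformation(self) -> pd.DataFrame:
        """Background transformation CFs (unknown initial class) per
        (region, destination class)."""
        rows = []
        for rid, mc in self.mc_by_region.items():
            mean, sd = mc.stats(mc.background_runs())
            for k, cid in enumerate(mc.class_ids):
                rows.append(dict(region_id=rid,
                                 flow_kind="transformation_background",
                                 lu2=cid, mean=float(mean[k]),
                                 stdev=float(sd[k]), units="t C.yr/ha"))
        return pd.DataFrame(rows)

    # -- aggregation and export ---------------------------------------------

    def by_country(self, records: pd.DataFrame | None = None) -> pd.DataFrame:
        """Area-weighted country aggregation of a per-region CF table
        (defaults to the occupation table)."""
        if records is None:
            records = self.foreground_occupation()
        cols = [c for c in records.columns if c != "units"]
        out = aggregation.aggregate_country(records[cols], self.model.regions)
        if "units" in records.columns:
            out["units"] = records["units"].iloc[0]
        return out

    def flow_table(self) -> pd.DataFrame:
        """Country-level CFs for the mapped land-use elementary flows."""
        return aggregation.build_flow_table(self.mc_by_region,
                                            self.model.regions,
                                            self.model.registry,
                                            load_flow_mapping())

    def export_rasters(self, directory, kind="occupation") -> list:
        """One GeoTIFF (mean, stdev bands) per class; returns written paths."""
        from pathlib import Path
        if self.model.grid is None:
            raise ValueError("model has no raster grid")
        outdir = Path(directory)
        outdir.mkdir(parents=True, exist_ok=True)
        table = (self.foreground_occupation() if kind == "occupation"
                 else self.background_transformation())
        paths = []
        for cid, sub in table.groupby("lu2"):
            values = {row["region_id"]: (row["mean"], row["stdev"])
                      for _, row in sub.iterrows()}
            path = outdir / f"{kind}_{cid}.tif"
            aggregation.write_raster(values, self.model.regions,
                                     self.model.grid, path)
            paths.append(path)
        return paths

    def export_impact_method(self, path) -> None:
        aggregation.export_impact_method(self.flow_table(), path)

    # -- presentation ---------------------------------------------------------

    def plot_regeneration(self, region_id: str, lu_from: str, ax=None):
        """Plot the deterministic regeneration curve of a class toward the
        region's PNV, with the attainable stocks marked."""
        import matplotlib.pyplot as plt
        pnv_row = self.pnv().set_index("region_id").loc[region_id]
        curve = self.model.transition_curve(region_id, lu_from,
                                            pnv_row["pnv_class_id"])
        if ax is None:
            _, ax = plt.subplots()
        ax.plot(curve.times, curve.soc, label=f"{lu_from} → PNV")
        ax.axhline(curve.asoc, ls="--", color="grey", label="ASOC (PNV)")
        ax.set_xlabel("time since transformation (yr)")
        ax.set_ylabel("SOC (t C/ha)")
        ax.legend()
        return ax

    def summary(self) -> str:
        """Plain-text overview of the fit."""
        occ = self.foreground_occupation()
        tra = self.foreground_transformation()
        bg = self.background_transformation()
        n_classes = len({cid for mc in self.mc_by_region.values()
                         for cid in mc.class_ids})
        lines = [
            "SOC depletion characterization",
            "=" * 46,
            f"regions:              {len(self.mc_by_region)}",
            f"land-use classes:     {n_classes}",
            f"Monte Carlo runs:     {self.n_runs}",
            "",
            f"{'table':<28}{'n':>6}{'mean':>12}{'sd(mean)':>12}",
            "-" * 58,
        ]
        for label, df in (("occupation (t C/ha)", occ),
                          ("transformation (t C.yr/ha)", tra),
                          ("background transf.", bg)):
            lines.append(f"{label:<28}{len(df):>6}{df['mean'].mean():>12.3f}"
                         f"{df['mean'].std():>12.3f}")
        return "\n".join(lines)

    def __repr__(self):
        return (f"<SOCDepletionResults: {len(self.mc_by_region)} regions, "
                f"{self.n_runs} runs>")
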