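import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

from soccf.aggregation import (aggregate_country, build_flow_table,
                               export_impact_method, import_impact_method,
                               read_raster, region_flow_values, write_raster)
from soccf.cli import main as cli_main
from soccf.exceptions import ConfigurationError
from soccf.uncertainty import PerturbationConfig, monte_carlo_region
from soccf.world import Grid, Region


@pytest.fixture(scope="module")
def mc_by_region(world6):
    cfg = PerturbationConfig(n_runs=5, seed=17)
    return {r.region_id: monte_carlo_region(r, world6.registry, cfg)
            for r in world6.regions}


class TestAggregateCountry:
    @staticmethod
    def _records(rows):
        return pd.DataFrame(rows, columns=["region_id", "flow_kind", "lu2",
                                           "mean", "stdev"])

    def test_single_region_country_passthrough(self, world6):
        region = world6.regions[0]
        rec = self._records([(region.region_id, "occupation", "urban",
                              12.5, 1.0)])
        out = aggregate_country(rec, [region])
        assert len(out) == 1
        assert out.iloc[0]["mean"] == 12.5
        assert out.iloc[0]["stdev"] == 1.0

    def test_equal_area_mean(self, world6):
        a = world6.regions[0].replace(area_ha=100.0, country="XX")
        b = world6.regions[1].replace(area_ha=100.0, country="XX")
        rec = self._records([(a.region_id, "occupation", "urban", 10.0, 3.0),
                             (b.region_id, "occupation", "urban", 30.0, 4.0)])
        out = aggregate_country(rec, [a, b])
        assert out.iloc[0]["mean"] == pytest.approx(20.0)
        # pooled spread: sqrt(mean of variances)
        assert out.iloc[0]["stdev"] == pytest.approx(
            np.sqrt((9.0 + 16.0) / 2))

    def test_country_mean_is_convex(self, world6):
        regions = [r.replace(country="YY") for r in world6.regions]
        vals = np.linspace(-5, 40, len(regions))
        rec = self._records([(r.region_id, "occupation", "urban", v, 0.0)
                             for r, v in zip(regions, vals)])
        out = aggregate_country(rec, regions)
        assert vals.min() <= out.iloc[0]["mean"] <= vals.max()

    def test_unknown_region_rejected(self, world6):
        rec = self._records([("nope", "occupation", "urban", 1.0, 0.0)])
        with pytest.raises(KeyError):
            aggregate_country(rec, world6.regions)


class TestFlowTable:
    def test_urban_flows_equal_urban_class_cf(self, world6, mc_by_region):
        """'Industrial area' resolves to the single urban class, so its flow
        value equals the urban occupation CF recomputed directly."""
        region = world6.regions[0]
        mc = mc_by_region[region.region_id]
        df = region_flow_values(mc, region, world6.registry)
        urban_col = mc.class_ids.index("urban")
        expected = mc.occupation_runs()[:, urban_col].mean()
        got = df[(df.flow_id == "7.2") & (df.flow_type == "occupation")]
        assert got["mean"].iloc[0] == pytest.approx(expected, rel=1e-12)

    def test_rainfed_arable_is_unweighted_class_average(self, world6,
                                                        mc_by_region):
        region = world6.regions[0]
        mc = mc_by_region[region.region_id]
        registry = world6.registry
        rainfed = [cid for cid in mc.class_ids
                   if registry[cid].category == "cropland"
                   and registry[cid].crop_type == "annual"
                   and registry[cid].management.water_regime.value == "rainfed"]
        occ = mc.occupation_runs()
        cols = [mc.class_ids.index(c) for c in rainfed]
        expected = occ[:, cols].mean(axis=1).mean()
        df = region_flow_values(mc, region, world6.registry)
        got = df[(df.flow_id == "5.1.2") & (df.flow_type == "occupation")]
        assert got["mean"].iloc[0] == pytest.approx(expected, rel=1e-12)

    def test_unspecified_natural_uses_min_asoc_forest(self, world6,
                                                      mc_by_region):
        region = world6.regions[5]  # has two feasible forests
        mc = mc_by_region[region.region_id]
        forests = [c for c in mc.class_ids if c.startswith("forest")]
        assert len(forests) >= 2
        asoc_mean = dict(zip(mc.class_ids, mc.asoc.mean(axis=0)))
        lowest = min(forests, key=lambda c: asoc_mean[c])
        df = region_flow_values(mc, region, world6.registry)
        got = df[(df.flow_id == "0.2") & (df.flow_type == "occupation")]
        col = mc.class_ids.index(lowest)
        assert got["mean"].iloc[0] == pytest.approx(
            mc.occupation_runs()[:, col].mean(), rel=1e-12)

    def test_country_table_unique_keys_and_units(self, world6, mc_by_region):
        table = build_flow_table(mc_by_region, world6.regions, world6.registry)
        assert not table.duplicated(["country", "flow_id", "flow_type"]).any()
        assert set(table["flow_type"]) == {"occupation", "transformation"}
        assert (table.loc[table.flow_type == "occupation", "units"]
                == "t C/ha").all()
        assert (table.loc[table.flow_type == "transformation", "units"]
                == "t C.yr/ha").all()
        # no water/wetland/bare flows can appear
        assert not table["flow_id"].astype(str).str.startswith("2").any()


class TestRaster:
    GRID = Grid(lat0=55.0, lon0=-30.0, n_rows=4, n_cols=4)

    @staticmethod
    def _regions(world6, n=3):
        out = []
        for i, r in enumerate(world6.regions[:n]):
            out.append(r.replace(footprint=(0, i, 2, 1)))
        return out

    def test_round_trip_bitwise(self, tmp_path, world6):
        regions = self._regions(world6)
        values = {r.region_id: (1.2345678901234 + i, 0.1 * i)
                  for i, r in enumerate(regions)}
        path = tmp_path / "cf.tif"
        write_raster(values, regions, self.GRID, path)
        data, grid, nodata = read_raster(path)
        assert data.shape == (2, 4, 4)
        for i, r in enumerate(regions):
            assert data[0, 0, i] == values[r.region_id][0]  # bitwise
            assert data[1, 0, i] == values[r.region_id][1]
        assert grid.pixel_size == 0.083
        assert grid.lat0 == 55.0 and grid.lon0 == -30.0

    def test_missing_region_is_nodata(self, tmp_path, world6):
        regions = self._regions(world6)
        values = {regions[0].region_id: (1.0, 0.0)}
        path = tmp_path / "partial.tif"
        write_raster(values, regions, self.GRID, path)
        data, _, nodata = read_raster(path)
        assert data[0, 0, 1] == nodata
        assert data[0, 3, 3] == nodata

    def test_overlapping_footprints_rejected(self, tmp_path, world6):
        regions = self._regions(world6)
        regions[1] = regions[1].replace(footprint=(0, 0, 1, 1))
        values = {r.region_id: (1.0, 0.0) for r in regions}
        with pytest.raises(ConfigurationError, match="claimed by both"):
            write_raster(values, regions, self.GRID, tmp_path / "x.tif")


class TestImpactMethodBundle:
    def test_empty_table_is_valid(self, tmp_path):
        empty = pd.DataFrame(columns=["country", "flow_id", "flow_type",
                                      "mean", "stdev"])
        path = tmp_path / "m.zip"
        export_impact_method(empty, path)
        assert import_impact_method(path).empty

    def test_factor_cardinality(self, tmp_path):
        table = pd.DataFrame([
            dict(country=c, flow_id=f, flow_type="occupation", mean=1.0,
                 stdev=0.1, name="x")
            for c in ("AA", "BB") for f in ("1", "3", "5")])
        path = tmp_path / "m.zip"
        export_impact_method(table, path)
        back = import_impact_method(path)
        assert len(back[back.flow_type == "occupation"]) == 6

    def test_round_trip(self, tmp_path, world6, mc_by_region):
        table = build_flow_table(mc_by_region, world6.regions, world6.registry)
        path = tmp_path / "m.zip"
        export_impact_method(table, path)
        back = import_impact_method(path)
        merged = table.merge(back, on=["country", "flow_id", "flow_type"],
                             suffixes=("", "_back"))
        assert len(merged) == len(table)
        assert np.allclose(merged["mean"], merged["mean_back"])
        assert np.allclose(merged["stdev"], merged["stdev_back"])

    def test_duplicate_keys_rejected(self, tmp_path):
        table = pd.DataFrame([
            dict(country="AA", flow_id="1", flow_type="occupation", mean=1.0,
                 stdev=0.0)] * 2)
        with pytest.raises(ConfigurationError):
            export_impact_method(table, tmp_path / "dup.zip")


class TestCLI:
    CONFIG = ("world:\n  n_regions: 4\n  n_countries: 2\n  seed: 5\n"
              "perturbation:\n  n_runs: 3\n")

    def test_missing_config_exits_2(self):
        runner = CliRunner()
        result = runner.invoke(cli_main,
                               ["cf-foreground", "--config", "missing.yml"])
        assert result.exit_code == 2

    def test_synth_writes_requested_regions(self, tmp_path):
        runner = CliRunner()
        result = runner.invoke(cli_main, ["synth", "--n-regions", "4",
                                          "--seed", "5", "--out",
                                          str(tmp_path / "w")])
        assert result.exit_code == 0, result.output
        regions = pd.read_csv(tmp_path / "w" / "regions.csv")
        assert len(regions) == 4

    def test_cf_foreground_deterministic(self, tmp_path):
        cfg = tmp_path / "demo.yml"
        cfg.write_text(self.CONFIG)
        runner = CliRunner()
        for out in ("a", "b"):
            result = runner.invoke(cli_main, [
                "cf-foreground", "--config", str(cfg), "--seed", "7",
                "--out", str(tmp_path / out)])
            assert result.exit_code == 0, result.output
        fa = (tmp_path / "a" / "foreground_occupation.csv").read_bytes()
        fb = (tmp_path / "b" / "foreground_occupation.csv").read_bytes()
        assert fa == fb
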