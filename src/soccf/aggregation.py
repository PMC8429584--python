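"""Country aggregation, elementary-flow tables, raster and exchange export.

Country-level CFs are area-weighted means over the regions where the class
(or class pair) is feasible; spreads combine as the square root of the
area-weighted mean of per-region variances (pooled form). Flow tables
resolve each land-use elementary flow per region — unweighted average over
its class set, or the extremal (minimum-ASOC) forest class — and aggregate
the resolved values to country level.

Rasters are single- or two-band (mean, stdev) GeoTIFFs on the native
0.083-degree geographic grid, pixel-center registered, WGS84, with an
explicit nodata value; written and read with tifffile plus standard GeoTIFF
tags.
"""

from __future__ import annotations

import json
import zipfile
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .exceptions import ConfigurationError, NoCharacterizationFactorError
from .lu_taxonomy import LandUseRegistry, load_flow_mapping, map_flow_to_classes
from .world import Grid, Region

__all__ = [
    "aggregate_country",
    "region_flow_values",
    "build_flow_table",
    "write_raster",
    "read_raster",
    "export_impact_method",
    "import_impact_method",
]

NODATA = -9999.0

# GeoTIFF tag codes
_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GEO_KEYS = 34735
_TAG_GDAL_NODATA = 42113

# GeoKeyDirectory: geographic model, pixel-is-point, WGS84
_GEO_KEYS = (1, 1, 0, 3,
             1024, 0, 1, 2,
             1025, 0, 1, 2,
             2048, 0, 1, 4326)


def aggregate_country(records: pd.DataFrame, regions,
                      value_col="mean", sd_col="stdev") -> pd.DataFrame:
    """Area-weighted country aggregation of per-region CF records.

    `records` must carry ``region_id``, the value/spread columns and any key
    columns (``flow_kind``, ``lu1``, ``lu2``, ``flow_id`` ...); grouping is
    by every non-value column except ``region_id`` plus the country. Weights
    are restricted to the regions actually carrying each record, so a flow
    infeasible everywhere in a country is omitted rather than zeroed.
    """
    lookup = {r.region_id: r for r in regions}
    missing = set(records["region_id"]) - set(lookup)
    if missing:
        raise KeyError(f"records reference unknown regions: {sorted(missing)}")
    df = records.copy()
    df["country"] = df["region_id"].map(lambda rid: lookup[rid].country)
    df["_area"] = df["region_id"].map(lambda rid: lookup[rid].area_ha)
    keys = [c for c in df.columns
            if c not in ("region_id", value_col, sd_col, "_area")]

    def _agg(g):
        w = g["_area"] / g["_area"].sum()
        out = {value_col: float((w * g[value_col]).sum()),
               "n_regions": len(g)}
        if sd_col in g:
            out[sd_col] = float(np.sqrt((w * g[sd_col] ** 2).sum()))
        return pd.Series(out)

    out = (df.groupby(keys, dropna=False).apply(_agg, include_groups=False)
           .reset_index())
    out["n_regions"] = out["n_regions"].astype(int)
    return out


def region_flow_values(mc, region: Region, registry: LandUseRegistry,
                       mapping: pd.DataFrame | None = None) -> pd.DataFrame:
    """Resolve every mapped elementary flow in one region.

    `mc` is an `uncertainty.RegionMonteCarlo`. Occupation flows take the
    per-run unweighted mean of the resolved classes' occupation CFs;
    transformation flows the per-run mean of their background transformation
    CFs — keeping all within-run pairing, so means and spreads are those of
    the resolved flow itself. The minimum-ASOC forest flow is resolved on
    mean ASOC. Flows whose class set is empty in the region are skipped.
    """
    if mapping is None:
        mapping = load_flow_mapping()
    col = {cid: k for k, cid in enumerate(mc.class_ids)}
    asoc_mean = dict(zip(mc.class_ids, mc.asoc.mean(axis=0)))
    occ = mc.occupation_runs()
    bg = mc.background_runs()
    rows = []
    for flow_id in mapping["flow_id"].astype(str):
        ids, _mode = map_flow_to_classes(flow_id, registry,
                                         feasible_ids=mc.class_ids,
                                         asoc_by_class=asoc_mean,
                                         mapping=mapping)
        if not ids:
            continue
        cols = [col[cid] for cid in ids]
        for flow_type, runs in (("occupation", occ), ("transformation", bg)):
            vals = runs[:, cols].mean(axis=1)
            sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
            rows.append(dict(region_id=region.region_id, flow_id=flow_id,
                             flow_type=flow_type, mean=float(vals.mean()),
                             stdev=sd, n_classes=len(ids)))
    return pd.DataFrame(rows)


def build_flow_table(mc_by_region: dict, regions, registry: LandUseRegistry,
                     mapping: pd.DataFrame | None = None) -> pd.DataFrame:
    """Country-level CF table over the mapped elementary flows.

    Resolves flows per region via `region_flow_values`, then aggregates to
    country level area-weighted. Every (country, flow_id, flow_type) appears
    at most once; flows infeasible throughout a country are absent.
    """
    if mapping is None:
        mapping = load_flow_mapping()
    lookup = {r.region_id: r for r in regions}
    frames = [region_flow_values(mc, lookup[rid], registry, mapping)
              for rid, mc in mc_by_region.items()]
    frames = [f for f in frames if not f.empty]
    if not frames:
        return pd.DataFrame(columns=["country", "flow_id", "flow_type",
                                     "mean", "stdev"])
    per_region = pd.concat(frames, ignore_index=True).drop(columns="n_classes")
    table = aggregate_country(per_region, regions)
    names = mapping.assign(flow_id=mapping["flow_id"].astype(str))
    table = table.merge(names[["flow_id", "name"]], on="flow_id", how="left")
    table["units"] = np.where(table["flow_type"] == "occupation",
                              "t C/ha", "t C.yr/ha")
    return table.sort_values(["country", "flow_type", "flow_id"],
                             ignore_index=True)


# ---------------------------------------------------------------------------
# Raster I/O

def write_raster(values_by_region: dict, regions, grid: Grid, path,
                 nodata: float = NODATA) -> None:
    """Write per-region values onto the grid as a GeoTIFF.

    ``values_by_region`` maps region_id to a scalar (one band) or a
    (mean, stdev) pair (two bands). Pixels of regions without a value are
    nodata. Overlapping footprints are an error listing the offenders.
    """
    lookup = {r.region_id: r for r in regions}
    sample = next(iter(values_by_region.values()), 0.0)
    n_bands = 2 if np.ndim(sample) else 1
    data = np.full((n_bands, grid.n_rows, grid.n_cols), nodata, dtype=np.float64)
    owner = {}
    for rid, value in values_by_region.items():
        region = lookup.get(rid)
        if region is None or region.footprint is None:
            raise KeyError(f"region {rid!r} unknown or without footprint")
        r0, c0, nr, nc = region.footprint
        for rr in range(r0, r0 + nr):
            for cc in range(c0, c0 + nc):
                if (rr, cc) in owner:
                    raise ConfigurationError(
                        f"pixel ({rr},{cc}) claimed by both "
                        f"{owner[(rr, cc)]!r} and {rid!r}")
                owner[(rr, cc)] = rid
        data[:, r0:r0 + nr, c0:c0 + nc] = np.reshape(value, (n_bands, 1, 1))
    extratags = [
        (_TAG_PIXEL_SCALE, "d", 3, (grid.pixel_size, grid.pixel_size, 0.0)),
        (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, grid.lon0, grid.lat0, 0.0)),
        (_TAG_GEO_KEYS, "H", len(_GEO_KEYS), _GEO_KEYS),
        (_TAG_GDAL_NODATA, "s", 0, str(nodata)),
    ]
    tifffile.imwrite(path, data, photometric="minisblack",
                     planarconfig="separate", extratags=extratags)


def read_raster(path):
    """Read a raster written by `write_raster`.

    Returns ``(data, grid, nodata)`` with data shaped (bands, rows, cols).
    """
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        data = tif.asarray()
        scale = page.tags[_TAG_PIXEL_SCALE].value
        tiepoint = page.tags[_TAG_TIEPOINT].value
        nodata = float(page.tags[_TAG_GDAL_NODATA].value)
    if data.ndim == 2:
        data = data[None, :, :]
    grid = Grid(lat0=float(tiepoint[4]), lon0=float(tiepoint[3]),
                n_rows=data.shape[1], n_cols=data.shape[2],
                pixel_size=float(scale[0]))
    if abs(scale[0] - scale[1]) > 1e-12:
        raise ValueError("non-square pixels are not supported")
    return data, grid, nodata


# ---------------------------------------------------------------------------
# Impact-method exchange bundle (JSON-LD-style zip)

_CATEGORY_META = {
    "occupation": dict(id="soc_depletion_occupation",
                       name="SOC depletion, land occupation",
                       unit="t C/ha"),
    "transformation": dict(id="soc_depletion_transformation",
                           name="SOC depletion, land transformation",
                           unit="t C.yr/ha"),
}


def export_impact_method(flow_table: pd.DataFrame, path,
                         method_name="SOC depletion (process-based)") -> None:
    """Write a country-level flow table as a zipped JSON impact method.

    One impact-category document per flow type; one factor object per
    (flow, country) with value, unit and a normal uncertainty (sd).
    Duplicate (flow_type, flow_id, country) keys are an error.
    """
    required = {"country", "flow_id", "flow_type", "mean", "stdev"}
    if not required.issubset(flow_table.columns):
        raise ValueError(f"flow table must carry columns {sorted(required)}")
    dup = flow_table.duplicated(["flow_type", "flow_id", "country"])
    if dup.any():
        bad = flow_table.loc[dup, ["flow_type", "flow_id", "country"]]
        raise ConfigurationError(
            f"duplicate factor keys:\n{bad.to_string(index=False)}")
    with zipfile.ZipFile(path, "w", zipfile.ZIP_DEFLATED) as zf:
        categories = []
        for flow_type, meta in _CATEGORY_META.items():
            sub = flow_table[flow_table["flow_type"] == flow_type]
            factors = [
                dict(flow_id=str(row["flow_id"]),
                     flow_name=str(row.get("name", "") or ""),
                     country=str(row["country"]), value=float(row["mean"]),
                     unit=meta["unit"],
                     uncertainty=dict(distribution="normal",
                                      sd=float(row["stdev"])))
                for row in sub.to_dict("records")
            ]
            categories.append(dict(**meta, n_factors=len(factors)))
            zf.writestr(f"factors_{flow_type}.json",
                        json.dumps(factors, indent=1))
        zf.writestr("method.json", json.dumps(
            dict(name=method_name, schema="soccf-impact-method-1",
                 impact_categories=categories), indent=1))


def import_impact_method(path) -> pd.DataFrame:
    """Re-import a bundle written by `export_impact_method` as a flow table."""
    rows = []
    with zipfile.ZipFile(path) as zf:
        method = json.loads(zf.read("method.json"))
        for cat in method["impact_categories"]:
            flow_type = ("occupation" if "occupation" in cat["id"]
                         else "transformation")
            for fac in json.loads(zf.read(f"factors_{flow_type}.json")):
                rows.append(dict(country=fac["country"],
                                 flow_id=fac["flow_id"],
                                 flow_type=flow_type, mean=fac["value"],
                                 stdev=fac["uncertainty"]["sd"],
                                 units=fac["unit"]))
    return pd.DataFrame(rows)
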