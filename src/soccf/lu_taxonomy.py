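"""Land-use class registry and elementary-flow classification key.

The registry ships as a versioned CSV fixture with 81 foreground classes:
63 cropland (crop x water regime x residue fate, one row per combination at
the baseline organic-fertilization scenario), 16 forest (leaf type x climate
zone), 1 grassland and 1 urban class. A second fixture carries the
classification key from the hierarchical land-use elementary flows used by
LCI databases
to class sets; water, wetland and bare-area flows are deliberately absent
and raise `NoCharacterizationFactorError`.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, NoCharacterizationFactorError

__all__ = [
    "WaterRegime",
    "ResidueFate",
    "FertilizationScenario",
    "ManagementRegime",
    "LandUseClass",
    "LandUseRegistry",
    "ElementaryFlow",
    "build_default_registry",
    "load_flow_mapping",
    "load_crop_coefficients",
    "residue_c_input",
    "map_flow_to_classes",
    "FERTILIZATION_MANURE_RATES",
]

#: Farmyard-manure C application (t C/ha/yr) per organic-fertilization
#: scenario. Configurable defaults; the scenarios are named levels only.
FERTILIZATION_MANURE_RATES = {"none": 0.0, "low": 1.0, "high": 2.0}


class WaterRegime(str, enum.Enum):
    RAINFED = "rainfed"
    IRRIGATED = "irrigated"


class ResidueFate(str, enum.Enum):
    LEFT = "left"
    REMOVED = "removed"
    NOT_APPLICABLE = "not_applicable"


class FertilizationScenario(str, enum.Enum):
    NONE = "none"
    LOW = "low"
    HIGH = "high"


@dataclass(frozen=True)
class ManagementRegime:
    """Cropland management attributes. ``residue_fate`` is only meaningful
    for cereal classes (both options exist); other crops carry
    NOT_APPLICABLE."""

    water_regime: WaterRegime
    residue_fate: ResidueFate
    fertilization: FertilizationScenario


@dataclass(frozen=True)
class LandUseClass:
    """One foreground land-use class.

    ``cover_calendar`` holds 12 binary soil-cover flags (1 = vegetated).
    ``dpm_rpm_ratio`` sets the decomposability split of plant inputs; it is
    unused (0) for the urban class, which receives no carbon inputs and is
    covered all year.
    """

    class_id: str
    category: str  # cropland | forest | grassland | urban
    crop_name: str | None = None
    crop_type: str | None = None  # annual | permanent (cropland only)
    forest_qualifier: str | None = None
    management: ManagementRegime | None = None
    dpm_rpm_ratio: float = 0.0
    cover_calendar: tuple = (1,) * 12

    def __post_init__(self):
        if self.category not in ("cropland", "forest", "grassland", "urban"):
            raise ConfigurationError(
                f"{self.class_id}: unknown category {self.category!r}")
        cal = tuple(int(v) for v in self.cover_calendar)
        if len(cal) != 12 or any(v not in (0, 1) for v in cal):
            raise ConfigurationError(
                f"{self.class_id}: cover_calendar must be 12 binary flags")
        object.__setattr__(self, "cover_calendar", cal)
        if self.category == "urban":
            if any(v != 1 for v in cal):
                raise ConfigurationError("urban class must be covered all year")
        elif self.dpm_rpm_ratio <= 0:
            raise ConfigurationError(
                f"{self.class_id}: dpm_rpm_ratio must be positive")
        if self.category == "cropland" and self.management is None:
            raise ConfigurationError(
                f"{self.class_id}: cropland classes need a management regime")

    @property
    def is_cereal(self) -> bool:
        return (self.management is not None
                and self.management.residue_fate != ResidueFate.NOT_APPLICABLE)


@dataclass(frozen=True)
class ElementaryFlow:
    """A land-use elementary flow (occupation or transformation)."""

    flow_id: str
    name: str
    flow_type: str  # occupation | transformation


class LandUseRegistry:
    """Ordered, id-keyed collection of `LandUseClass` objects."""

    def __init__(self, classes):
        self._classes = {}
        for cls in classes:
            if cls.class_id in self._classes:
                raise ConfigurationError(f"duplicate class id {cls.class_id}")
            self._classes[cls.class_id] = cls

    def __len__(self):
        return len(self._classes)

    def __iter__(self):
        return iter(self._classes.values())

    def __contains__(self, class_id):
        return class_id in self._classes

    def __getitem__(self, class_id) -> LandUseClass:
        try:
            return self._classes[class_id]
        except KeyError:
            raise KeyError(f"unknown land-use class {class_id!r}") from None

    @property
    def class_ids(self):
        return list(self._classes)

    def filter(self, **attrs):
        """Classes matching all given attribute values, e.g.
        ``registry.filter(category='forest')``."""
        out = []
        for cls in self:
            ok = True
            for key, want in attrs.items():
                if key in ("water_regime", "residue_fate", "fertilization"):
                    got = getattr(cls.management, key, None) if cls.management else None
                    got = got.value if got is not None else None
                else:
                    got = getattr(cls, key)
                if got != want:
                    ok = False
                    break
            if ok:
                out.append(cls)
        return out

    def subset(self, class_ids) -> "LandUseRegistry":
        return LandUseRegistry([self[cid] for cid in class_ids])


def _read_packaged_csv(name: str) -> pd.DataFrame:
    with resources.files("soccf.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh)


def build_default_registry() -> LandUseRegistry:
    """Load the packaged 81-class registry fixture.

    Raises `ConfigurationError` naming the offending entry on any malformed
    row.
    """
    df = _read_packaged_csv("lu_classes.csv")
    classes = []
    for _, row in df.iterrows():
        cid = str(row["class_id"])
        try:
            management = None
            if row["category"] == "cropland":
                management = ManagementRegime(
                    water_regime=WaterRegime(row["water_regime"]),
                    residue_fate=ResidueFate(row["residue_fate"]),
                    fertilization=FertilizationScenario(row["fert_scenario"]),
                )
            cover = tuple(int(row[f"cover_m{m:02d}"]) for m in range(1, 13))
            classes.append(LandUseClass(
                class_id=cid,
                category=str(row["category"]),
                crop_name=str(row["crop_name"]) if isinstance(row["crop_name"], str) and row["crop_name"] else None,
                crop_type=str(row["crop_type"]) if isinstance(row["crop_type"], str) and row["crop_type"] else None,
                forest_qualifier=str(row["forest_qualifier"]) if isinstance(row["forest_qualifier"], str) and row["forest_qualifier"] else None,
                management=management,
                dpm_rpm_ratio=float(row["dpm_rpm_ratio"]),
                cover_calendar=cover,
            ))
        except (ValueError, ConfigurationError) as exc:
            raise ConfigurationError(f"malformed registry entry {cid!r}: {exc}") from exc
    return LandUseRegistry(classes)


def load_flow_mapping() -> pd.DataFrame:
    """The packaged elementary-flow classification key
    (flow_id, name, selector)."""
    return _read_packaged_csv("flow_mapping.csv")


def load_crop_coefficients() -> pd.DataFrame:
    """Per-crop residue coefficients (slope, intercept, root:shoot, C
    fraction) plus the synthetic-world reference yield, indexed by crop."""
    return _read_packaged_csv("crop_coefficients.csv").set_index("crop_name")


def residue_c_input(yield_dm: float, crop_coefs) -> float:
    """Annual plant C input (t C/ha/yr) from a crop yield via residue
    accounting.

    ``aboveground = yield*slope + intercept``;
    ``belowground = (yield + aboveground) * root_shoot_ratio``;
    ``C = (aboveground*(1 - residue_removed_fraction) + belowground) *
    c_fraction``. A removed fraction of 1 encodes full residue removal — the
    belowground share is still returned to the soil.

    `crop_coefs` is a mapping with keys slope, intercept, root_shoot_ratio,
    c_fraction and optional residue_removed_fraction (default 0).
    """
    if yield_dm < 0:
        raise ValueError("yield must be non-negative")
    slope = float(crop_coefs["slope"])
    intercept = float(crop_coefs["intercept"])
    rs = float(crop_coefs["root_shoot_ratio"])
    cf = float(crop_coefs["c_fraction"])
    removed = float(crop_coefs.get("residue_removed_fraction", 0.0)
                    if hasattr(crop_coefs, "get")
                    else crop_coefs["residue_removed_fraction"])
    if not 0.0 < cf <= 1.0:
        raise ValueError("c_fraction must lie in (0, 1]")
    if not 0.0 <= removed <= 1.0:
        raise ValueError("residue_removed_fraction must lie in [0, 1]")
    aboveground = yield_dm * slope + intercept
    belowground = (yield_dm + aboveground) * rs
    return (aboveground * (1.0 - removed) + belowground) * cf


# ---------------------------------------------------------------------------
# Elementary-flow resolution

def _selector_classes(selector: str, registry: LandUseRegistry):
    crops = [c for c in registry if c.category == "cropland"]
    if selector == "urban":
        return [c for c in registry if c.category == "urban"]
    if selector == "grassland":
        return [c for c in registry if c.category == "grassland"]
    if selector in ("forest_all", "forest_min_asoc"):
        return [c for c in registry if c.category == "forest"]
    if selector == "cropland_all":
        return crops
    if selector == "annual_all":
        return [c for c in crops if c.crop_type == "annual"]
    if selector == "annual_rainfed":
        return [c for c in crops if c.crop_type == "annual"
                and c.management.water_regime is WaterRegime.RAINFED]
    if selector == "annual_irrigated":
        return [c for c in crops if c.crop_type == "annual"
                and c.management.water_regime is WaterRegime.IRRIGATED]
    if selector == "permanent_all":
        return [c for c in crops if c.crop_type == "permanent"]
    if selector == "permanent_rainfed":
        return [c for c in crops if c.crop_type == "permanent"
                and c.management.water_regime is WaterRegime.RAINFED]
    if selector == "permanent_irrigated":
        return [c for c in crops if c.crop_type == "permanent"
                and c.management.water_regime is WaterRegime.IRRIGATED]
    if selector == "rice_irrigated":
        return [c for c in crops if c.crop_name == "rice"
                and c.management.water_regime is WaterRegime.IRRIGATED]
    raise ConfigurationError(f"unknown flow selector {selector!r}")


def map_flow_to_classes(flow_id: str, registry: LandUseRegistry,
                        feasible_ids=None, asoc_by_class=None,
                        mapping: pd.DataFrame | None = None):
    """Resolve an elementary flow to a class set and resolution mode.

    Returns ``(class_ids, mode)`` where mode is ``'average'`` (the CF is the
    unweighted mean over the set) or ``'extremal_min_asoc'`` (the single
    forest class with minimum attainable SOC; requires `asoc_by_class`).
    `feasible_ids` restricts the set to classes feasible in a region; an
    empty result after restriction returns ``([], mode)``. Unmapped flow ids
    (water, wetland, bare areas) raise `NoCharacterizationFactorError`.
    """
    if mapping is None:
        mapping = load_flow_mapping()
    row = mapping.loc[mapping["flow_id"].astype(str) == str(flow_id)]
    if row.empty:
        raise NoCharacterizationFactorError(
            f"no SOC-depletion CF is defined for elementary flow {flow_id!r}")
    selector = row.iloc[0]["selector"]
    classes = _selector_classes(selector, registry)
    ids = [c.class_id for c in classes]
    if feasible_ids is not None:
        feas = set(feasible_ids)
        ids = [cid for cid in ids if cid in feas]
    if selector == "forest_min_asoc":
        if not ids:
            return [], "extremal_min_asoc"
        if asoc_by_class is None:
            raise ValueError(
                "flow requires per-class attainable SOC to pick the minimum")
        ids = [min(ids, key=lambda cid: (asoc_by_class[cid], cid))]
        return ids, "extremal_min_asoc"
    return sorted(ids), "average"
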