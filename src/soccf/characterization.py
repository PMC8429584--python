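"""Occupation and transformation characterization factors.

Occupation CF (t C/ha): the attainable-SOC gap between potential natural
vegetation (PNV) and the occupying class,

    CF_occ = ASOC_PNV - ASOC_LU2.

Transformation CF (t C·yr/ha): the difference between the accumulated SOC
deficits (area between each class's regeneration-to-PNV curve and ASOC_PNV,
integrated to infinity via the fitted exponential tail),

    CF_tr = Impact_LU2 - Impact_LU1,

so a positive CF means the transition to LU2 depletes SOC. With both
impacts referenced to the same PNV the factors are exactly antisymmetric:
CF(A→B) = −CF(B→A). Background transformation CFs replace the unknown
initial class by the land-use-share-weighted average of category-mean
impacts in the region.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import soc_curves
from .exceptions import ConfigurationError
from .lu_taxonomy import LandUseRegistry
from .rothc import DEFAULT_PARAMS, RothCParams
from .soc_curves import SOCCurve
from .world import SHARE_TO_CATEGORY, Region

__all__ = [
    "PNVAssignment",
    "ImpactValue",
    "CFRecord",
    "RegionCharacterization",
    "select_pnv",
    "occupation_cf",
    "regeneration_impact",
    "transformation_cf_foreground",
    "transformation_cf_background",
    "characterize_region",
]


@dataclass(frozen=True)
class PNVAssignment:
    """The potential-natural-vegetation class of a region: the feasible
    forest or grassland class with maximum attainable SOC (ties broken by
    class id)."""

    region_id: str
    pnv_class_id: str
    asoc_pnv: float


@dataclass(frozen=True)
class ImpactValue:
    """Accumulated regeneration deficit (t C·yr/ha) of one class against the
    regional PNV: trapezoidal integral over the simulated window plus the
    analytic tail."""

    value: float
    simulated: float
    tail: float
    asoc_pnv: float
    class_id: str = ""


@dataclass(frozen=True)
class CFRecord:
    """One characterization factor. Positive values are SOC depletion.
    Units: t C/ha for occupation, t C·yr/ha for transformation."""

    region_id: str
    flow_kind: str  # occupation | transformation_foreground | transformation_background
    lu2: str
    lu1: str | None = None
    mean: float = 0.0
    stdev: float = 0.0

    @property
    def units(self) -> str:
        return "t C/ha" if self.flow_kind == "occupation" else "t C.yr/ha"


def select_pnv(region: Region, registry: LandUseRegistry,
               params: RothCParams = DEFAULT_PARAMS,
               asoc_by_class=None) -> PNVAssignment:
    """Pick the PNV class: argmax of attainable SOC over the feasible forest
    and grassland classes; exact ties resolve to the lexicographically
    smaller id. `asoc_by_class` may supply precomputed ASOC values."""
    candidates = [cid for cid in region.feasible_classes
                  if registry[cid].category in ("forest", "grassland")]
    if not candidates:
        raise ConfigurationError(
            f"region {region.region_id!r} has no feasible forest or "
            "grassland class; PNV is undefined")
    if asoc_by_class is None:
        asoc_by_class = {cid: soc_curves.attainable_soc(region, cid, registry,
                                                        params)
                         for cid in candidates}
    best = min(candidates, key=lambda cid: (-asoc_by_class[cid], cid))
    return PNVAssignment(region_id=region.region_id, pnv_class_id=best,
                         asoc_pnv=float(asoc_by_class[best]))


def occupation_cf(asoc_pnv: float, asoc_lu2: float) -> float:
    """Occupation CF: ``ASOC_PNV − ASOC_LU2`` (t C/ha); negative values are
    SOC gains relative to natural vegetation."""
    if asoc_pnv < 0 or asoc_lu2 < 0:
        raise ValueError("attainable SOC stocks must be non-negative")
    return asoc_pnv - asoc_lu2


def regeneration_impact(curve: SOCCurve, asoc_pnv: float,
                        floor=1e-9) -> ImpactValue:
    """Accumulated deficit between ASOC_PNV and a regeneration-to-PNV curve.

    Trapezoidal integral of ``asoc_pnv − soc(t)`` over the simulated monthly
    window plus the analytic tail ``deficit(t_end)/k`` from the fitted
    exponential rate; the terminal deficit is taken seasonal-cycle-removed,
    since with ASOC defined as the annual mean of the equilibrium orbit the
    raw seasonal oscillation integrates to zero over each settled year. A
    curve resting at ASOC_PNV contributes zero. A nonzero terminal deficit
    without a valid rate is an error (the infinite integral would be
    undefined).
    """
    if abs(curve.asoc - asoc_pnv) > 1e-6 * max(1.0, abs(asoc_pnv)):
        raise ValueError(
            "curve does not regenerate to the supplied PNV stock "
            f"(curve ASOC {curve.asoc:.6g} vs ASOC_PNV {asoc_pnv:.6g})")
    deficit = asoc_pnv - curve.soc
    simulated = float(np.trapezoid(deficit, curve.times))
    terminal = curve.terminal_deficit
    if abs(terminal) <= floor:
        tail = 0.0
    else:
        if curve.k is None or curve.k <= 0:
            raise ValueError(
                "cannot integrate regeneration tail: terminal deficit "
                f"{terminal:.3g} t C/ha with no positive fitted rate")
        tail = terminal / curve.k
    return ImpactValue(value=simulated + tail, simulated=simulated, tail=tail,
                       asoc_pnv=asoc_pnv, class_id=curve.lu_from)


def transformation_cf_foreground(impact_lu1: ImpactValue,
                                 impact_lu2: ImpactValue) -> float:
    """Foreground transformation CF: ``Impact_LU2 − Impact_LU1`` (t C·yr/ha),
    both impacts referenced to the same PNV."""
    if abs(impact_lu1.asoc_pnv - impact_lu2.asoc_pnv) > 1e-9 * max(
            1.0, abs(impact_lu1.asoc_pnv)):
        raise ValueError("impacts reference different PNV stocks")
    return impact_lu2.value - impact_lu1.value


def background_initial_impact(region: Region, registry: LandUseRegistry,
                              impacts_by_class: dict) -> float:
    """Share-weighted mean impact of the unknown initial land use.

    ``Impact_LU1 = Σ_category share · mean(impact over feasible classes of
    that category)``, with shares renormalized over the categories that are
    both present in the region's share map and feasible. All-zero usable
    shares is an error.
    """
    cat_means = {}
    for share_name, category in SHARE_TO_CATEGORY.items():
        vals = [impacts_by_class[cid].value for cid in region.feasible_classes
                if registry[cid].category == category
                and cid in impacts_by_class]
        if vals:
            cat_means[share_name] = float(np.mean(vals))
    usable = {name: region.lu_shares.get(name, 0.0)
              for name in cat_means if region.lu_shares.get(name, 0.0) > 0}
    total = sum(usable.values())
    if total <= 0:
        raise ConfigurationError(
            f"region {region.region_id!r}: no usable land-use shares for the "
            "background initial impact")
    return sum(share / total * cat_means[name]
               for name, share in usable.items())


def transformation_cf_background(region: Region, lu_to: str,
                                 impacts_by_class: dict,
                                 registry: LandUseRegistry) -> float:
    """Background transformation CF to ``lu_to`` (t C·yr/ha): the class's
    impact minus the share-weighted regional initial impact."""
    if lu_to not in impacts_by_class:
        raise KeyError(f"no regeneration impact available for {lu_to!r}")
    base = background_initial_impact(region, registry, impacts_by_class)
    return impacts_by_class[lu_to].value - base


@dataclass
class RegionCharacterization:
    """Deterministic per-region characterization: ASOC per class, the PNV
    assignment, regeneration-to-PNV impacts, and derived CFs."""

    region_id: str
    class_ids: list
    asoc: dict
    pnv: PNVAssignment
    impacts: dict
    curves: dict | None = None

    def occupation(self, lu2: str) -> float:
        return occupation_cf(self.pnv.asoc_pnv, self.asoc[lu2])

    def transformation(self, lu1: str, lu2: str) -> float:
        return transformation_cf_foreground(self.impacts[lu1],
                                            self.impacts[lu2])


def characterize_region(region: Region, registry: LandUseRegistry,
                        params: RothCParams = DEFAULT_PARAMS,
                        growth_years=soc_curves.GROWTH_YEARS,
                        keep_curves=False) -> RegionCharacterization:
    """Full deterministic characterization of one region.

    Computes every feasible class's ASOC, selects the PNV, simulates each
    class's regeneration-to-PNV curve (through the growth ramp when the PNV
    is a forest) and integrates the impacts.
    """
    class_ids = [cid for cid in region.feasible_classes if cid in registry]
    asoc = {cid: soc_curves.attainable_soc(region, cid, registry, params)
            for cid in class_ids}
    pnv = select_pnv(region, registry, params, asoc_by_class=asoc)
    impacts = {}
    curves = {} if keep_curves else None
    for cid in class_ids:
        curve = soc_curves.simulate_transition(
            region, cid, pnv.pnv_class_id, registry, params,
            growth_years=growth_years)
        imp = regeneration_impact(curve, pnv.asoc_pnv)
        impacts[cid] = ImpactValue(value=imp.value, simulated=imp.simulated,
                                   tail=imp.tail, asoc_pnv=imp.asoc_pnv,
                                   class_id=cid)
        if keep_curves:
            curves[cid] = curve
    return RegionCharacterization(region_id=region.region_id,
                                  class_ids=class_ids, asoc=asoc, pnv=pnv,
                                  impacts=impacts, curves=curves)
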