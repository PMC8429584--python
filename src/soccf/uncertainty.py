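"""Monte Carlo propagation of intra-region input variability.

Each run draws one perturbed copy of a region's inputs from normal
distributions centred on the regional values (truncated to physical ranges)
and repeats the full characterization on it. All factors within a run share
the same draw, so per-run identities — transformation antisymmetry, zero
occupation CF of the PNV class — survive the averaging exactly. CF means
are arithmetic means over runs and spreads are sample standard deviations
(ddof=1).
"""

from __future__ import annotations

import logging
import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np

from .characterization import (RegionCharacterization,
                               background_initial_impact, characterize_region)
from .environment import MonthlyClimate, SoilProfile
from .exceptions import SoccfError
from .lu_taxonomy import LandUseRegistry
from .rothc import DEFAULT_PARAMS, RothCParams
from .world import Region

__all__ = ["PerturbationConfig", "sample_inputs", "RegionMonteCarlo",
           "monte_carlo_region", "monte_carlo_cfs"]

logger = logging.getLogger(__name__)

#: Fraction of failed runs above which the Monte Carlo aborts.
MAX_FAILURE_FRACTION = 0.2


@dataclass(frozen=True)
class PerturbationConfig:
    """Spread of the intra-region input distributions.

    ``tavg_sd`` is an additive standard deviation (°C, one shared draw for
    all months); the others are relative (coefficient-of-variation) spreads
    applied as one multiplicative draw per input family per run. Defaults
    are plausible intra-region magnitudes and are fully configurable.
    """

    tavg_sd: float = 1.0
    precip_cv: float = 0.10
    clay_cv: float = 0.10
    soc_init_cv: float = 0.15
    c_input_cv: float = 0.10
    n_runs: int = 100
    seed: int = 0

    def __post_init__(self):
        if min(self.tavg_sd, self.precip_cv, self.clay_cv, self.soc_init_cv,
               self.c_input_cv) < 0:
            raise ValueError("perturbation spreads must be non-negative")
        if self.n_runs < 1:
            raise ValueError("n_runs must be at least 1")

    @property
    def is_degenerate(self) -> bool:
        return (self.tavg_sd == 0 and self.precip_cv == 0 and self.clay_cv == 0
                and self.soc_init_cv == 0 and self.c_input_cv == 0)


def _run_rng(config: PerturbationConfig, region_id: str,
             run_index: int) -> np.random.Generator:
    """Deterministic per-(seed, region, run) stream."""
    key = zlib.crc32(region_id.encode("utf-8"))
    seq = np.random.SeedSequence(entropy=int(config.seed) & 0x7FFFFFFF,
                                 spawn_key=(key, int(run_index)))
    return np.random.default_rng(seq)


def sample_inputs(region: Region, config: PerturbationConfig,
                  run_index: int) -> Region:
    """One perturbed copy of a region, deterministic given
    (seed, region_id, run_index).

    Temperature shifts by a shared additive normal draw; precipitation,
    clay, initial SOC and plant C inputs scale by one truncated-normal
    multiplicative draw each. IOM scales with the initial-SOC draw so the
    invariant 0 ≤ iom ≤ soc_init is preserved exactly.
    """
    rng = _run_rng(config, region.region_id, run_index)
    dt = rng.normal(0.0, config.tavg_sd) if config.tavg_sd > 0 else 0.0
    f_precip = _pos_factor(rng, config.precip_cv)
    f_clay = _pos_factor(rng, config.clay_cv)
    f_soc = _pos_factor(rng, config.soc_init_cv)
    f_cin = _pos_factor(rng, config.c_input_cv)
    if (dt == 0.0 and f_precip == f_clay == f_soc == f_cin == 1.0):
        return region
    climate = MonthlyClimate(tavg=region.climate.tavg + dt,
                             precip=region.climate.precip * f_precip,
                             day_length=region.climate.day_length,
                             days_in_month=region.climate.days_in_month)
    soil = SoilProfile(clay=float(np.clip(region.soil.clay * f_clay, 0, 100)),
                       soc_init=region.soil.soc_init * f_soc,
                       depth=region.soil.depth,
                       iom=region.soil.iom * f_soc)
    c_inputs = {cid: v * f_cin for cid, v in region.c_inputs.items()}
    return region.replace(climate=climate, soil=soil, c_inputs=c_inputs)


def _pos_factor(rng, cv: float) -> float:
    if cv <= 0:
        return 1.0
    return float(max(0.0, rng.normal(1.0, cv)))


@dataclass
class RegionMonteCarlo:
    """Per-run characterization arrays for one region.

    ``asoc`` and ``impact`` are (n_runs, n_classes) in ``class_ids`` order;
    ``pnv_index`` holds each run's PNV column; ``bg_impact`` the run's
    share-weighted initial impact. Occupation and transformation CF
    statistics are derived from these paired arrays.
    """

    region_id: str
    class_ids: list
    asoc: np.ndarray
    impact: np.ndarray
    pnv_index: np.ndarray
    bg_impact: np.ndarray
    n_failed: int = 0
    deterministic: RegionCharacterization | None = None

    @property
    def n_runs(self) -> int:
        return self.asoc.shape[0]

    def occupation_runs(self) -> np.ndarray:
        """(n_runs, n_classes) occupation CFs, each run against its own PNV."""
        pnv_asoc = self.asoc[np.arange(self.n_runs), self.pnv_index]
        return pnv_asoc[:, None] - self.asoc

    def transformation_runs(self, i: int, j: int) -> np.ndarray:
        return self.impact[:, j] - self.impact[:, i]

    def background_runs(self) -> np.ndarray:
        """(n_runs, n_classes) background transformation CFs."""
        return self.impact - self.bg_impact[:, None]

    @staticmethod
    def stats(runs: np.ndarray):
        mean = runs.mean(axis=0)
        sd = (runs.std(axis=0, ddof=1) if runs.shape[0] > 1
              else np.zeros_like(mean))
        return mean, sd


def monte_carlo_region(region: Region, registry: LandUseRegistry,
                       config: PerturbationConfig,
                       params: RothCParams = DEFAULT_PARAMS,
                       growth_years=20) -> RegionMonteCarlo:
    """Repeat the full characterization of one region over perturbed inputs.

    Failed runs are dropped with a logged reason; more than
    `MAX_FAILURE_FRACTION` failures abort. With ``n_runs == 1`` the spread
    is zero by construction (a warning is emitted).
    """
    if config.n_runs == 1:
        warnings.warn("n_runs=1: standard deviations are identically zero",
                      UserWarning, stacklevel=2)
    class_ids = list(region.feasible_classes)
    col = {cid: k for k, cid in enumerate(class_ids)}
    asoc_rows, impact_rows, pnv_rows, bg_rows = [], [], [], []
    n_failed = 0
    for run in range(config.n_runs):
        try:
            sampled = (region if config.is_degenerate
                       else sample_inputs(region, config, run))
            rc = characterize_region(sampled, registry, params,
                                     growth_years=growth_years)
            asoc_rows.append([rc.asoc[cid] for cid in class_ids])
            impact_rows.append([rc.impacts[cid].value for cid in class_ids])
            pnv_rows.append(col[rc.pnv.pnv_class_id])
            bg_rows.append(background_initial_impact(sampled, registry,
                                                     rc.impacts))
        except Exception as exc:  # noqa: BLE001 - logged and accounted
            n_failed += 1
            logger.warning("region %s run %d failed: %s",
                           region.region_id, run, exc)
    if n_failed > MAX_FAILURE_FRACTION * config.n_runs:
        raise SoccfError(
            f"region {region.region_id!r}: {n_failed}/{config.n_runs} Monte "
            "Carlo runs failed")
    return RegionMonteCarlo(region_id=region.region_id, class_ids=class_ids,
                            asoc=np.asarray(asoc_rows),
                            impact=np.asarray(impact_rows),
                            pnv_index=np.asarray(pnv_rows, dtype=int),
                            bg_impact=np.asarray(bg_rows),
                            n_failed=n_failed)


def monte_carlo_cfs(region: Region, registry: LandUseRegistry,
                    config: PerturbationConfig,
                    params: RothCParams = DEFAULT_PARAMS):
    """Monte Carlo CF records for one region.

    Returns a list of `characterization.CFRecord` with means and sample
    standard deviations over runs: occupation CFs for every feasible class,
    foreground transformation CFs for every ordered pair (one direction,
    lu1 < lu2; the reverse is the negative), and background transformation
    CFs to every feasible class.
    """
    from .characterization import CFRecord  # local to avoid cycle at import

    mc = monte_carlo_region(region, registry, config, params)
    records = []
    occ_mean, occ_sd = mc.stats(mc.occupation_runs())
    for k, cid in enumerate(mc.class_ids):
        records.append(CFRecord(region_id=region.region_id,
                                flow_kind="occupation", lu2=cid,
                                mean=float(occ_mean[k]),
                                stdev=float(occ_sd[k])))
    for i, lu1 in enumerate(mc.class_ids):
        for j, lu2 in enumerate(mc.class_ids):
            if lu1 >= lu2:
                continue
            runs = mc.transformation_runs(i, j)
            mean, sd = mc.stats(runs[:, None])
            records.append(CFRecord(region_id=region.region_id,
                                    flow_kind="transformation_foreground",
                                    lu1=lu1, lu2=lu2, mean=float(mean[0]),
                                    stdev=float(sd[0])))
    bg_mean, bg_sd = mc.stats(mc.background_runs())
    for k, cid in enumerate(mc.class_ids):
        records.append(CFRecord(region_id=region.region_id,
                                flow_kind="transformation_background",
                                lu2=cid, mean=float(bg_mean[k]),
                                stdev=float(bg_sd[k])))
    return records
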