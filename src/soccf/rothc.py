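"""Five-pool RothC soil-carbon turnover.

Monthly first-order decay of four active pools (DPM, RPM, BIO, HUM) plus an
inert pool (IOM), with multiplicative temperature / moisture / soil-cover
rate modifiers, clay-dependent CO2 partitioning, and an analytic annual
steady state.

The pool-update map for one month is affine in the active-pool vector, so a
constant annual climate cycle yields a 12-step affine map whose fixed point
is the attainable (equilibrium) stock. Both the step-by-step simulator and
the analytic steady state are built from the same monthly transfer matrices.

All stocks in t C/ha, decay constants in 1/yr, monthly time step.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .environment import MonthlyClimate, SoilProfile
from .exceptions import NoEquilibriumError

__all__ = [
    "ACTIVE_POOLS",
    "RothCParams",
    "PoolState",
    "MoistureState",
    "RateModifiers",
    "temperature_modifier",
    "moisture_modifier",
    "max_tsmd",
    "co2_partition_ratio",
    "step_month",
    "run",
    "steady_state",
    "monthly_rate_modifiers",
    "monthly_transfer_matrices",
    "annual_affine_map",
]

#: Order of the active pools in every array representation.
ACTIVE_POOLS = ("dpm", "rpm", "bio", "hum")


@dataclass(frozen=True)
class RothCParams:
    """RothC 26.3 constants, collected in one swappable object.

    Decay constants (1/yr): DPM 10, RPM 0.3, BIO 0.66, HUM 0.02. Decayed C
    splits CO2 : (BIO+HUM) as x : 1 with ``x = 1.67 (1.85 + 1.60
    exp(-0.0786 clay))``; the retained share splits 46 % BIO / 54 % HUM.
    Farmyard-manure inputs partition 49/49/2 % into DPM/RPM/HUM. The soil
    cover modifier is 0.6 when vegetated and 1.0 when bare; the moisture
    modifier declines linearly from 1 to ``b_min = 0.2`` between 0.444 of
    the maximum topsoil moisture deficit and the maximum itself. Default
    DPM/RPM allocation of plant inputs: 1.44 arable, 0.25 forest, 0.67
    grassland.
    """

    k_dpm: float = 10.0
    k_rpm: float = 0.3
    k_bio: float = 0.66
    k_hum: float = 0.02
    bio_fraction: float = 0.46
    hum_fraction: float = 0.54
    manure_partition: tuple = (0.49, 0.49, 0.02)  # DPM, RPM, HUM
    b_min: float = 0.2
    tsmd_onset: float = 0.444        # fraction of max TSMD where b starts falling
    bare_cap_divisor: float = 1.8    # bare-soil TSMD cap = max_tsmd / 1.8
    pet_effectiveness: float = 0.75  # open-pan correction in TSMD accumulation
    cover_factor_covered: float = 0.6
    cover_factor_bare: float = 1.0
    dpm_rpm_arable: float = 1.44
    dpm_rpm_forest: float = 0.25
    dpm_rpm_grassland: float = 0.67

    def __post_init__(self):
        if min(self.k_dpm, self.k_rpm, self.k_bio, self.k_hum) <= 0:
            raise ValueError("decay constants must be positive")
        if abs(self.bio_fraction + self.hum_fraction - 1.0) > 1e-12:
            raise ValueError("bio_fraction + hum_fraction must equal 1")

    @property
    def decay_constants(self) -> np.ndarray:
        return np.array([self.k_dpm, self.k_rpm, self.k_bio, self.k_hum])


DEFAULT_PARAMS = RothCParams()


@dataclass
class PoolState:
    """Carbon stock of the five compartments (t C/ha)."""

    dpm: float = 0.0
    rpm: float = 0.0
    bio: float = 0.0
    hum: float = 0.0
    iom: float = 0.0

    def __post_init__(self):
        if min(self.dpm, self.rpm, self.bio, self.hum, self.iom) < 0:
            raise ValueError("pool stocks must be non-negative")

    @property
    def total_soc(self) -> float:
        return self.dpm + self.rpm + self.bio + self.hum + self.iom

    def active(self) -> np.ndarray:
        """Active pools as a vector in `ACTIVE_POOLS` order."""
        return np.array([self.dpm, self.rpm, self.bio, self.hum])

    @classmethod
    def from_active(cls, active, iom: float) -> "PoolState":
        d, r, b, h = (float(v) for v in active)
        return cls(dpm=d, rpm=r, bio=b, hum=h, iom=float(iom))


@dataclass
class MoistureState:
    """Accumulated topsoil moisture deficit (TSMD), mm."""

    tsmd: float = 0.0

    def __post_init__(self):
        if self.tsmd < 0:
            raise ValueError("tsmd must be non-negative")


@dataclass(frozen=True)
class RateModifiers:
    """Multiplicative decay modifiers for one month."""

    a: float  # temperature
    b: float  # moisture
    c: float  # soil cover

    def __post_init__(self):
        if self.a < 0 or self.b < 0 or self.c < 0:
            raise ValueError("rate modifiers must be non-negative")

    @property
    def abc(self) -> float:
        return self.a * self.b * self.c


def temperature_modifier(tavg):
    """Temperature rate modifier ``a = 47.91 / (1 + exp(106.06/(T+18.27)))``
    for T above −18.27 °C, zero below (frozen-soil convention)."""
    t = np.asarray(tavg, dtype=float)
    out = np.zeros_like(t)
    warm = t > -18.27
    out[warm] = 47.91 / (1.0 + np.exp(106.06 / (t[warm] + 18.27)))
    return out[()]


def max_tsmd(clay: float, depth: float = 23.0) -> float:
    """Maximum topsoil moisture deficit (mm) for a vegetated soil:
    ``(20 + 1.3 clay − 0.01 clay²) · depth/23``."""
    return (20.0 + 1.3 * clay - 0.01 * clay**2) * depth / 23.0


def moisture_modifier(precip: float, pet: float, clay: float, depth: float,
                      covered: bool, state: MoistureState,
                      params: RothCParams = DEFAULT_PARAMS):
    """Advance the TSMD bookkeeping one month and return ``(b, new_state)``.

    The deficit grows by ``max(0, 0.75·PET − precip)`` up to the applicable
    cap (the full maximum under vegetation, max/1.8 on bare soil — a bare
    deficit inherited above its cap is held, not grown) and is drawn down by
    excess precipitation. ``b`` is 1 while the deficit is below 0.444 of the
    vegetated maximum and declines linearly to ``b_min`` at the maximum.
    """
    mt = max_tsmd(clay, depth)
    cap = mt if covered else mt / params.bare_cap_divisor
    deficit = params.pet_effectiveness * pet - precip
    tsmd = state.tsmd
    if deficit > 0:
        tsmd = tsmd if tsmd >= cap else min(cap, tsmd + deficit)
    else:
        tsmd = max(0.0, tsmd + deficit)
    onset = params.tsmd_onset * mt
    if tsmd <= onset:
        b = 1.0
    else:
        b = params.b_min + (1.0 - params.b_min) * (mt - tsmd) / (mt - onset)
        b = min(1.0, max(params.b_min, b))
    return b, MoistureState(tsmd=tsmd)


def co2_partition_ratio(clay: float) -> float:
    """Ratio x of CO2 to (BIO+HUM) formed from decayed carbon."""
    return 1.67 * (1.85 + 1.60 * np.exp(-0.0786 * clay))


def step_month(state: PoolState, mods: RateModifiers, plant_input: float,
               manure_input: float, dpm_rpm_ratio: float, clay: float,
               params: RothCParams = DEFAULT_PARAMS):
    """One monthly step: first-order decay of each active pool, CO2/BIO/HUM
    partition of the decayed carbon, then addition of the month's inputs
    (inputs are not decayed in their month of arrival). Returns
    ``(new_state, co2)``; mass balance ``ΔSOC = inputs − co2`` holds exactly.
    """
    if plant_input < 0 or manure_input < 0:
        raise ValueError("carbon inputs must be non-negative")
    pools = state.active()
    survival = np.exp(-params.decay_constants * mods.abc / 12.0)
    decayed = pools * (1.0 - survival)
    total_decayed = float(decayed.sum())
    x = co2_partition_ratio(clay)
    co2 = total_decayed * x / (1.0 + x)
    retained = total_decayed / (1.0 + x)
    new = pools * survival
    new[2] += params.bio_fraction * retained
    new[3] += params.hum_fraction * retained
    if plant_input > 0:
        f_dpm = dpm_rpm_ratio / (1.0 + dpm_rpm_ratio)
        new[0] += plant_input * f_dpm
        new[1] += plant_input * (1.0 - f_dpm)
    if manure_input > 0:
        m_dpm, m_rpm, m_hum = params.manure_partition
        new[0] += manure_input * m_dpm
        new[1] += manure_input * m_rpm
        new[3] += manure_input * m_hum
    return PoolState.from_active(new, state.iom), co2


def monthly_rate_modifiers(climate: MonthlyClimate, cover_calendar, clay: float,
                           depth: float = 23.0,
                           params: RothCParams = DEFAULT_PARAMS,
                           max_cycles: int = 60):
    """Spin the TSMD bookkeeping to its periodic annual cycle and return the
    per-month modifiers ``(a, b, c)`` as three length-12 arrays.

    The TSMD recursion depends only on climate and cover, so under a
    repeating annual cycle it reaches a periodic orbit after a few cycles
    (iterated here to 1e-10 mm or `max_cycles`).
    """
    cover = np.asarray(cover_calendar, dtype=float)
    if cover.shape != (12,) or not np.all(np.isin(cover, (0.0, 1.0))):
        raise ValueError("cover_calendar must be 12 binary flags")
    a = temperature_modifier(climate.tavg)
    c = np.where(cover > 0, params.cover_factor_covered,
                 params.cover_factor_bare)
    b = np.ones(12)
    state = MoistureState(0.0)
    for _ in range(max_cycles):
        start = state.tsmd
        for m in range(12):
            b[m], state = moisture_modifier(
                climate.precip[m], climate.pet[m], clay, depth,
                bool(cover[m]), state, params)
        if abs(state.tsmd - start) < 1e-10:
            break
    return np.asarray(a, dtype=float), b, c


def monthly_transfer_matrices(a, b, c, clay: float, dpm_rpm_ratio: float,
                              plant_monthly, manure_monthly,
                              params: RothCParams = DEFAULT_PARAMS):
    """Affine monthly pool updates ``s -> M_m s + v_m`` plus the CO2 row.

    Returns ``(M, v, co2_w)`` with shapes (12,4,4), (12,4) and (12,4):
    ``co2_w[m] @ s`` is the CO2 respired in month m from a start-of-month
    active vector ``s`` (inputs arriving that month do not respire).
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    c = np.asarray(c, float)
    plant = np.asarray(plant_monthly, float)
    manure = np.asarray(manure_monthly, float)
    if np.any(plant < 0) or np.any(manure < 0):
        raise ValueError("carbon inputs must be non-negative")
    x = co2_partition_ratio(clay)
    abc = a * b * c                                     # (12,)
    survival = np.exp(-np.outer(abc, params.decay_constants) / 12.0)  # (12,4)
    loss = 1.0 - survival
    M = np.zeros((12, 4, 4))
    idx = np.arange(4)
    M[:, idx, idx] = survival
    M[:, 2, :] += params.bio_fraction * loss / (1.0 + x)
    M[:, 3, :] += params.hum_fraction * loss / (1.0 + x)
    f_dpm = dpm_rpm_ratio / (1.0 + dpm_rpm_ratio) if dpm_rpm_ratio > 0 else 0.0
    alloc_plant = np.array([f_dpm, 1.0 - f_dpm, 0.0, 0.0])
    m_dpm, m_rpm, m_hum = params.manure_partition
    alloc_manure = np.array([m_dpm, m_rpm, 0.0, m_hum])
    v = plant[:, None] * alloc_plant + manure[:, None] * alloc_manure
    co2_w = loss * x / (1.0 + x)
    return M, v, co2_w


def annual_affine_map(M, v):
    """Compose 12 monthly affine maps into the annual map ``s -> A s + u``."""
    A = np.eye(4)
    u = np.zeros(4)
    for m in range(12):
        u = M[m] @ u + v[m]
        A = M[m] @ A
    return A, u


def run(state: PoolState, climate: MonthlyClimate, cover_calendar,
        plant_monthly, manure_monthly, dpm_rpm_ratio: float,
        soil: SoilProfile, years: int, params: RothCParams = DEFAULT_PARAMS,
        depth: float | None = None):
    """Simulate `years` years under a repeating annual cycle.

    Returns ``(pools, co2)`` where ``pools`` has shape (12·years, 5) holding
    the end-of-month stocks (DPM, RPM, BIO, HUM, IOM) and ``co2`` the monthly
    respiration. The moisture bookkeeping starts from zero deficit and runs
    continuously (no spin-up), so the first months may differ slightly from
    the periodic-cycle modifiers used by `steady_state`; the long-run limits
    agree.
    """
    if years < 1:
        raise ValueError("years must be >= 1")
    depth = soil.depth if depth is None else depth
    plant = np.asarray(plant_monthly, float)
    manure = np.asarray(manure_monthly, float)
    a = temperature_modifier(climate.tavg)
    cover = np.asarray(cover_calendar, dtype=float)
    c = np.where(cover > 0, params.cover_factor_covered,
                 params.cover_factor_bare)
    pools = np.empty((12 * years, 5))
    co2 = np.empty(12 * years)
    moisture = MoistureState(0.0)
    s = state
    i = 0
    for _ in range(years):
        for m in range(12):
            bm, moisture = moisture_modifier(
                climate.precip[m], climate.pet[m], soil.clay, depth,
                bool(cover[m]), moisture, params)
            s, q = step_month(s, RateModifiers(a[m], bm, c[m]),
                              plant[m], manure[m], dpm_rpm_ratio,
                              soil.clay, params)
            pools[i] = (s.dpm, s.rpm, s.bio, s.hum, s.iom)
            co2[i] = q
            i += 1
    return pools, co2


def steady_state(climate: MonthlyClimate, cover_calendar, plant_monthly,
                 manure_monthly, dpm_rpm_ratio: float, clay: float,
                 iom: float, params: RothCParams = DEFAULT_PARAMS,
                 depth: float = 23.0) -> PoolState:
    """Equilibrium pools under a constant annual cycle.

    Solves the fixed point of the composed annual affine map,
    ``(I − A) s = u``. With all decay shut off and nonzero inputs the system
    is singular and `NoEquilibriumError` is raised.
    """
    a, b, c = monthly_rate_modifiers(climate, cover_calendar, clay, depth,
                                     params)
    M, v, _ = monthly_transfer_matrices(a, b, c, clay, dpm_rpm_ratio,
                                        plant_monthly, manure_monthly, params)
    A, u = annual_affine_map(M, v)
    if not np.any(u):
        return PoolState.from_active(np.zeros(4), iom)
    lhs = np.eye(4) - A
    try:
        s = np.linalg.solve(lhs, u)
    except np.linalg.LinAlgError as exc:
        raise NoEquilibriumError(
            "annual transfer map has no fixed point (all rate modifiers zero "
            "with nonzero carbon inputs)") from exc
    if not np.all(np.isfinite(s)):
        raise NoEquilibriumError("equilibrium solve produced non-finite pools")
    s = np.maximum(s, 0.0)  # clip roundoff-negative pools
    return PoolState.from_active(s, iom)
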