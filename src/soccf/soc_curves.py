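"""Attainable SOC equilibria and regeneration / transition curves.

For every (region, class) pair the monthly pool update under a constant
annual climate cycle is an affine map, so the attainable SOC (ASOC) is the
fixed point of the composed annual map and any transition trajectory can be
evaluated in closed form from the eigendecomposition of the annual transfer
matrix. Curves are produced on a monthly grid until the total stock comes
within ``tol_reg`` of the destination ASOC (or a hard horizon), and an
exponential tail ``asoc - D exp(-k t)`` is fitted to the trailing samples so
the infinite-time regeneration deficit can be integrated analytically.

Transitions into forest classes are simulated through an explicit growth
period with linearly ramped carbon inputs before the mature dynamics take
over; because pools can only decay toward (never through) zero, the stock
never falls below the inert pool.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import rothc
from .exceptions import SimulationWarning
from .lu_taxonomy import (FERTILIZATION_MANURE_RATES, LandUseClass,
                          LandUseRegistry)
from .rothc import DEFAULT_PARAMS, PoolState, RothCParams
from .world import Region

__all__ = [
    "TOL_REG",
    "HORIZON_YEARS",
    "FOREST_DEPTH_CM",
    "TransitionSpec",
    "SOCCurve",
    "ClassDynamics",
    "build_dynamics",
    "class_monthly_inputs",
    "attainable_soc",
    "equilibrium_pools",
    "simulate_transition",
    "forest_growth_curve",
    "fit_exponential_tail",
]

#: Convergence tolerance on |SOC - ASOC| that defines the regeneration time
#: t_reg (t C/ha) and stops the simulated window.
TOL_REG = 0.1
#: Hard simulation horizon (years); the fitted tail carries the remainder.
HORIZON_YEARS = 500
#: Default forest growth period (years) with a linear C-input ramp.
GROWTH_YEARS = 20
GROWTH_RAMP_START = 0.1  # initial fraction of mature C input
#: Simulated topsoil depth under forest (cm); other classes use the soil's.
FOREST_DEPTH_CM = 30.0

_DEFICIT_FLOOR = 1e-9


@dataclass(frozen=True)
class TransitionSpec:
    """A land-use transition in one region."""

    region_id: str
    lu_from: str
    lu_to: str


@dataclass
class SOCCurve:
    """A simulated SOC trajectory with its fitted exponential tail.

    ``times`` (years, monthly grid starting at the transition onset
    ``t_start``) and ``soc`` (t C/ha) cover the simulated window; ``asoc``
    is the destination attainable stock (annual mean of the equilibrium
    orbit), ``k`` the fitted tail rate (1/yr, None for a constant curve),
    ``t_reg`` the first time the deviation from the destination equilibrium
    drops below the convergence tolerance (None if never reached in the
    window). ``soc_deseasonalized`` carries the series with the within-year
    equilibrium cycle removed; it equals ``soc`` for constant-climate
    configurations and is what the tail is fitted on.
    """

    times: np.ndarray
    soc: np.ndarray
    asoc: float
    k: float | None
    t_reg: float | None
    region_id: str = ""
    lu_from: str = ""
    lu_to: str = ""
    t_start: float = 0.0
    converged: bool = True
    soc_deseasonalized: np.ndarray | None = None

    def __post_init__(self):
        if self.soc_deseasonalized is None:
            self.soc_deseasonalized = self.soc

    @property
    def terminal_deficit(self) -> float:
        """Remaining deficit at the window end, seasonal cycle removed."""
        return float(self.asoc - self.soc_deseasonalized[-1])


@dataclass
class ClassDynamics:
    """Precomputed affine dynamics of one class in one region.

    Under a seasonal cycle the equilibrium is a periodic *orbit*, not a
    constant: ``orbit`` holds its month-end active totals and ``asoc`` is
    the annual (trapezoidal) mean of the orbit plus the inert pool —
    the stock the class maintains on average at equilibrium. Transition
    curves are assessed against their deviation from this orbit, which
    decays cleanly, rather than against the oscillating raw series.
    """

    lu_class: LandUseClass
    clay: float
    iom: float
    depth: float
    M: np.ndarray       # (12,4,4) monthly transfer matrices
    v: np.ndarray       # (12,4) monthly input vectors
    A: np.ndarray       # annual transfer matrix
    u: np.ndarray       # annual input vector
    eq: np.ndarray      # (4,) equilibrium active pools at the year start
    asoc: float
    Ct: np.ndarray      # (12,4): total-SOC weights of cumulative monthly maps
    dt: np.ndarray      # (12,): total-SOC contribution of within-year inputs
    orbit: np.ndarray   # (12,) month-end equilibrium active totals


def class_monthly_inputs(region: Region, lu_class: LandUseClass,
                         manure_rates=None):
    """Monthly plant and manure C inputs (t C/ha/month) for a class.

    The annual plant input from ``region.c_inputs`` is distributed across
    the year proportionally to the soil-cover calendar; manure (set by the
    class's organic-fertilization scenario) follows the same calendar. The
    urban class receives no input.
    """
    plant = np.zeros(12)
    manure = np.zeros(12)
    if lu_class.category == "urban":
        return plant, manure
    annual = float(region.c_inputs.get(lu_class.class_id, 0.0))
    cover = np.asarray(lu_class.cover_calendar, dtype=float)
    weights = cover / cover.sum() if cover.sum() else np.full(12, 1 / 12)
    plant = annual * weights
    rates = FERTILIZATION_MANURE_RATES if manure_rates is None else manure_rates
    if lu_class.management is not None:
        manure = rates[lu_class.management.fertilization.value] * weights
    return plant, manure


def build_dynamics(region: Region, lu_class: LandUseClass,
                   params: RothCParams = DEFAULT_PARAMS,
                   manure_rates=None) -> ClassDynamics:
    """Assemble the affine monthly/annual dynamics of a class in a region."""
    depth = FOREST_DEPTH_CM if lu_class.category == "forest" else region.soil.depth
    plant, manure = class_monthly_inputs(region, lu_class, manure_rates)
    a, b, c = rothc.monthly_rate_modifiers(
        region.climate, lu_class.cover_calendar, region.soil.clay, depth,
        params)
    M, v, _ = rothc.monthly_transfer_matrices(
        a, b, c, region.soil.clay, lu_class.dpm_rpm_ratio, plant, manure,
        params)
    A, u = rothc.annual_affine_map(M, v)
    if np.any(u):
        eq = np.linalg.solve(np.eye(4) - A, u)
        eq = np.maximum(eq, 0.0)
    else:
        eq = np.zeros(4)
    # cumulative within-year maps, reduced to total-SOC weights
    Ct = np.empty((12, 4))
    dt = np.empty(12)
    C = np.eye(4)
    d = np.zeros(4)
    for m in range(12):
        d = M[m] @ d + v[m]
        C = M[m] @ C
        Ct[m] = C.sum(axis=0)
        dt[m] = d.sum()
    iom = region.soil.iom
    orbit = Ct @ eq + dt                       # month-end equilibrium totals
    p0 = float(eq.sum())                       # year-start (= month-12) total
    asoc_active = (p0 / 2.0 + orbit[:-1].sum() + orbit[-1] / 2.0) / 12.0
    return ClassDynamics(lu_class=lu_class, clay=region.soil.clay, iom=iom,
                         depth=depth, M=M, v=v, A=A, u=u, eq=eq,
                         asoc=float(asoc_active + iom), Ct=Ct, dt=dt,
                         orbit=orbit)


def equilibrium_pools(region: Region, lu_class_or_id, registry=None,
                      params: RothCParams = DEFAULT_PARAMS) -> PoolState:
    """Equilibrium `PoolState` of a class in a region (urban: inert only)."""
    lu_class = _resolve(lu_class_or_id, registry)
    if lu_class.category == "urban":
        return PoolState(iom=region.soil.iom)
    dyn = build_dynamics(region, lu_class, params)
    return PoolState.from_active(dyn.eq, region.soil.iom)


def attainable_soc(region: Region, lu_class_or_id, registry=None,
                   params: RothCParams = DEFAULT_PARAMS) -> float:
    """Attainable SOC (t C/ha): the equilibrium total stock of a class under
    the region's constant climate and soil; the inert pool for urban."""
    lu_class = _resolve(lu_class_or_id, registry)
    if lu_class.category == "urban":
        return float(region.soil.iom)
    return build_dynamics(region, lu_class, params).asoc


def _resolve(lu_class_or_id, registry) -> LandUseClass:
    if isinstance(lu_class_or_id, LandUseClass):
        return lu_class_or_id
    if registry is None:
        raise ValueError("a registry is required to resolve a class id")
    return registry[lu_class_or_id]


def _yearly_states(A, u, eq, s0, n_years):
    """States at the start of years 0..n_years via the eigendecomposition of
    the annual map (falls back to direct iteration if ill-conditioned)."""
    delta0 = s0 - eq
    try:
        lam, P = np.linalg.eig(A)
        coeff = np.linalg.solve(P, delta0.astype(complex))
        if np.linalg.cond(P) > 1e10:
            raise np.linalg.LinAlgError
        powers = lam[None, :] ** np.arange(n_years + 1)[:, None]
        states = np.real((powers * coeff) @ P.T) + eq
    except np.linalg.LinAlgError:
        states = np.empty((n_years + 1, 4))
        s = s0.astype(float).copy()
        delta = s - eq
        states[0] = s
        for n in range(1, n_years + 1):
            delta = A @ delta
            states[n] = delta + eq
    return states


def _transition_curve(dyn: ClassDynamics, s0, tol_reg=TOL_REG,
                      horizon=HORIZON_YEARS, growth_scales=None):
    """Monthly SOC trajectory from active pools ``s0`` under ``dyn``.

    ``growth_scales`` optionally scales the input vector during the first
    years (forest growth ramp). Returns
    (times, soc, soc_deseasonalized, converged, t_reg).
    """
    iom = dyn.iom
    asoc = dyn.asoc
    growth_scales = np.asarray(growth_scales if growth_scales is not None
                               else [], dtype=float)
    g = len(growth_scales)
    # start-of-year states through the (possibly scaled-input) growth phase
    states_growth = np.empty((g + 1, 4))
    s = np.asarray(s0, dtype=float)
    states_growth[0] = s
    for y in range(g):
        s = dyn.A @ s + growth_scales[y] * dyn.u
        states_growth[y + 1] = s
    states_tail = _yearly_states(dyn.A, dyn.u, dyn.eq, s, horizon - g)
    states = np.vstack([states_growth[:-1], states_tail])  # (horizon+1, 4)
    # convergence is judged on the deviation from the equilibrium *orbit*
    # (year-start phase), which decays monotonically in the tail; raw
    # deficits against the annual-mean ASOC oscillate seasonally forever
    p0 = float(dyn.eq.sum())
    dev_yearly = np.abs(states.sum(axis=1) - p0)
    above = np.flatnonzero(dev_yearly >= tol_reg)
    converged = bool(dev_yearly[-1] < tol_reg)
    if above.size == 0:
        n_end = 2
    else:
        n_end = int(min(horizon, max(2, above[-1] + 2)))
    if not converged:
        warnings.warn(
            f"transition did not reach ASOC within {horizon} years; "
            "the fitted exponential tail carries the remainder",
            SimulationWarning, stacklevel=2)
    # monthly expansion over the simulated window
    scales = np.ones(n_end)
    scales[:min(g, n_end)] = growth_scales[:min(g, n_end)]
    monthly = states[:n_end] @ dyn.Ct.T + scales[:, None] * dyn.dt[None, :]
    soc = np.empty(12 * n_end + 1)
    soc[0] = states[0].sum() + iom
    soc[1:] = monthly.ravel() + iom
    times = np.arange(12 * n_end + 1) / 12.0
    # remove the within-year equilibrium cycle: what remains decays to asoc
    orbit_series = np.empty_like(soc)
    orbit_series[0] = p0 + iom
    orbit_series[1:] = np.tile(dyn.orbit + iom, n_end)
    detrended = soc - orbit_series + asoc
    below = np.flatnonzero(np.abs(asoc - detrended) < tol_reg)
    t_reg = float(times[below[0]]) if below.size else None
    return times, soc, detrended, converged, t_reg


def fit_exponential_tail(times, soc, asoc, min_samples=24,
                         floor=_DEFICIT_FLOOR, max_window=240):
    """Regeneration rate k (1/yr) from the log-linear tail of the deficit.

    Least-squares slope of ``ln|asoc - soc(t)|`` against t, negated, over the
    trailing window of up to `max_window` monthly samples whose deficit is
    above the numerical floor and of constant sign (the window shrinks to
    the post-crossing samples if the deficit changes sign). A constant curve
    (deficit everywhere at the floor) has no rate: returns None.
    """
    times = np.asarray(times, dtype=float)
    deficit = asoc - np.asarray(soc, dtype=float)
    usable = np.abs(deficit) > floor
    if not usable.any():
        return None
    last = int(np.flatnonzero(usable)[-1])
    sign = np.sign(deficit[last])
    ok = usable & (np.sign(deficit) == sign)
    # trailing contiguous run ending at `last`
    bad = np.flatnonzero(~ok[:last + 1])
    start = int(bad[-1]) + 1 if bad.size else 0
    start = max(start, last + 1 - max_window)
    idx = np.arange(start, last + 1)
    if idx.size < 2:
        return None
    if idx.size < min_samples and idx.size < usable.sum():
        warnings.warn("exponential tail fitted on fewer than "
                      f"{min_samples} constant-sign samples",
                      SimulationWarning, stacklevel=2)
    slope = np.polyfit(times[idx], np.log(np.abs(deficit[idx])), 1)[0]
    return float(-slope)


def simulate_transition(region: Region, lu_from, lu_to,
                        registry: LandUseRegistry | None = None,
                        params: RothCParams = DEFAULT_PARAMS,
                        tol_reg=TOL_REG, horizon=HORIZON_YEARS,
                        growth_years=GROWTH_YEARS) -> SOCCurve:
    """SOC trajectory of a land-use transition.

    The source class contributes only its equilibrium pools (regeneration is
    assumed to start from a system in equilibrium; an urban source starts
    from the inert stock alone); dynamics, cover and inputs are those of the
    destination class. Transitions into forest run through the growth-period
    input ramp.
    """
    cls_from = _resolve(lu_from, registry)
    cls_to = _resolve(lu_to, registry)
    for cls in (cls_from, cls_to):
        if region.feasible_classes and cls.class_id not in region.feasible_classes:
            raise ValueError(
                f"class {cls.class_id!r} is not feasible in region "
                f"{region.region_id!r}")
    dyn_to = build_dynamics(region, cls_to, params)
    if cls_from.class_id == cls_to.class_id:
        s0 = dyn_to.eq
        growth_scales = None
    else:
        s0 = equilibrium_pools(region, cls_from, params=params).active()
        growth_scales = _growth_ramp(growth_years) \
            if cls_to.category == "forest" else None
    times, soc, detrended, converged, t_reg = _transition_curve(
        dyn_to, s0, tol_reg=tol_reg, horizon=horizon,
        growth_scales=growth_scales)
    k = fit_exponential_tail(times, detrended, dyn_to.asoc)
    if ((k is None or k <= 0)
            and abs(dyn_to.asoc - detrended[-1]) > _DEFICIT_FLOOR):
        # residual deficit but no usable log-linear window (e.g. the deficit
        # crossed zero just before the window end): fall back on the exact
        # asymptotic rate of the affine dynamics, -ln of the dominant
        # eigenvalue of the annual transfer matrix
        lam = float(np.max(np.abs(np.linalg.eigvals(dyn_to.A))))
        if 0.0 < lam < 1.0:
            k = -np.log(lam)
    return SOCCurve(times=times, soc=soc, asoc=dyn_to.asoc, k=k, t_reg=t_reg,
                    region_id=region.region_id, lu_from=cls_from.class_id,
                    lu_to=cls_to.class_id, converged=converged,
                    soc_deseasonalized=detrended)


def _growth_ramp(growth_years: int) -> np.ndarray:
    """Linear C-input ramp from GROWTH_RAMP_START to 1 over the growth
    period."""
    if growth_years <= 1:
        return np.ones(max(growth_years, 0))
    return np.linspace(GROWTH_RAMP_START, 1.0, growth_years)


def forest_growth_curve(region: Region, lu_from, forest_to,
                        registry: LandUseRegistry | None = None,
                        growth_years=GROWTH_YEARS,
                        params: RothCParams = DEFAULT_PARAMS,
                        tol_reg=TOL_REG, horizon=HORIZON_YEARS) -> SOCCurve:
    """Transition curve into a forest class: explicit growth-period
    simulation with ramped inputs, then the exponential approach to the
    forest ASOC. The trajectory is bounded below by the inert stock by
    construction (pools decay toward zero, never through it)."""
    cls_to = _resolve(forest_to, registry)
    if cls_to.category != "forest":
        raise ValueError("forest_growth_curve requires a forest destination")
    return simulate_transition(region, lu_from, cls_to, registry, params,
                               tol_reg=tol_reg, horizon=horizon,
                               growth_years=growth_years)
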