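"""Climate and soil input types.

Provides the Thornthwaite potential-evapotranspiration calculation used to
drive the moisture rate modifier, and the pedotransfer estimating the inert
organic matter (IOM) pool from a total SOC stock.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DAYS_IN_MONTH",
    "MonthlyClimate",
    "SoilProfile",
    "thornthwaite_pet",
    "iom_from_soc",
]

#: Calendar days per month (non-leap year).
DAYS_IN_MONTH = np.array([31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31])

# Default IOM pedotransfer coefficients, iom = alpha * soc**beta (t C/ha).
IOM_ALPHA = 0.049
IOM_BETA = 1.139


def thornthwaite_pet(tavg, day_length, days_in_month=None):
    """Monthly potential evapotranspiration (mm/month), Thornthwaite (1948).

    Heat index ``I = sum((T_m/5)**1.514)`` over months with ``T_m > 0``;
    ``PET_m = 16 (L_m/12) (N_m/30) (10 T_m / I)**a`` for ``T_m > 0`` and 0
    otherwise, with the classic cubic exponent ``a(I)``. The unadjusted 1948
    form is used (no high-temperature modification); the day-length and
    month-length corrections enter through ``L_m`` and ``N_m``.

    Parameters
    ----------
    tavg : array-like, shape (12,)
        Mean monthly air temperature, °C.
    day_length : array-like, shape (12,)
        Mean day length, hours.
    days_in_month : array-like, shape (12,), optional
        Days per month; defaults to the non-leap calendar.
    """
    tavg = np.asarray(tavg, dtype=float)
    day_length = np.asarray(day_length, dtype=float)
    if days_in_month is None:
        days_in_month = DAYS_IN_MONTH
    days_in_month = np.asarray(days_in_month, dtype=float)
    if not (tavg.shape == day_length.shape == days_in_month.shape == (12,)):
        raise ValueError("thornthwaite_pet expects three length-12 vectors")

    warm = tavg > 0.0
    heat_index = float(np.sum((tavg[warm] / 5.0) ** 1.514))
    pet = np.zeros(12)
    if heat_index == 0.0:
        return pet  # every month at or below freezing
    a = (6.75e-7 * heat_index**3
         - 7.71e-5 * heat_index**2
         + 1.792e-2 * heat_index
         + 0.49239)
    pet[warm] = (16.0 * (day_length[warm] / 12.0) * (days_in_month[warm] / 30.0)
                 * (10.0 * tavg[warm] / heat_index) ** a)
    return pet


def iom_from_soc(soc_total, alpha=IOM_ALPHA, beta=IOM_BETA):
    """Inert-organic-matter stock (t C/ha) from total SOC via a power-law
    pedotransfer, clipped to ``[0, soc_total]``."""
    soc = np.asarray(soc_total, dtype=float)
    if np.any(soc < 0):
        raise ValueError("soc_total must be non-negative")
    return np.clip(alpha * soc**beta, 0.0, soc)[()]


@dataclass
class MonthlyClimate:
    """Twelve-month climate normals driving the turnover simulator.

    PET is computed on construction from temperature and day length unless
    supplied explicitly.
    """

    tavg: np.ndarray
    precip: np.ndarray
    day_length: np.ndarray
    days_in_month: np.ndarray = field(default_factory=lambda: DAYS_IN_MONTH.copy())
    pet: np.ndarray | None = None

    def __post_init__(self):
        for name in ("tavg", "precip", "day_length", "days_in_month"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (12,):
                raise ValueError(f"{name} must have 12 monthly entries")
            setattr(self, name, arr)
        if np.any(self.precip < 0):
            raise ValueError("precipitation must be non-negative")
        if np.any((self.day_length < 0) | (self.day_length > 24)):
            raise ValueError("day length must lie in [0, 24] hours")
        if self.pet is None:
            self.pet = thornthwaite_pet(self.tavg, self.day_length,
                                        self.days_in_month)
        else:
            self.pet = np.asarray(self.pet, dtype=float)
            if self.pet.shape != (12,) or np.any(self.pet < 0):
                raise ValueError("pet must be 12 non-negative entries")


@dataclass
class SoilProfile:
    """Topsoil description: clay fraction, depth, initial stock and IOM.

    ``depth`` is the simulated topsoil depth in cm (23 cm, the standard
    arable/grassland convention; forest dynamics use 30 cm — see
    `soc_curves`). If ``iom`` is omitted it is estimated from ``soc_init``
    by the power-law pedotransfer.
    """

    clay: float
    soc_init: float
    depth: float = 23.0
    iom: float | None = None

    def __post_init__(self):
        if not 0.0 <= self.clay <= 100.0:
            raise ValueError("clay must be a percentage in [0, 100]")
        if self.soc_init < 0:
            raise ValueError("soc_init must be non-negative")
        if self.iom is None:
            self.iom = float(iom_from_soc(self.soc_init))
        if not 0.0 <= self.iom <= self.soc_init:
            raise ValueError("iom must satisfy 0 <= iom <= soc_init")
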