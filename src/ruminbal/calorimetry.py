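"""Indirect calorimetry for respiration-chamber gas exchange.

Turns chamber concentration traces into daily gas volumes and derives the
downstream quantities: fermentative vs. metabolic CO2 partition, metabolic
respiratory quotient, net fat and carbohydrate oxidation, and heat
production.

Unit conventions
----------------
* gas concentrations: dimensionless volume fractions,
* airflow: m^3/h,
* daily gas volumes: L/d,
* urinary nitrogen: g/d,
* heat production: kJ/d.

Gas volumes are treated as already expressed at one consistent reference
state (dry, standard temperature and pressure); an optional multiplicative
``correction`` factor is exposed where volumes are integrated, defaulting
to 1.0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GASES",
    "StoichiometricConstants",
    "ChamberTrace",
    "GasVolumes",
    "GasExchangeDaily",
    "NegativeOxidationWarning",
    "integrate_gas_exchange",
    "fermentative_co2",
    "metabolic_co2",
    "metabolic_rq",
    "fat_oxidation",
    "carbohydrate_oxidation",
    "heat_production",
    "summarize_day",
]

#: gases tracked by a chamber trace, in canonical order
GASES = ("o2", "co2", "ch4")


class NegativeOxidationWarning(UserWarning):
    """A net oxidation rate came out negative (net synthesis regime)."""


@dataclass(frozen=True)
class StoichiometricConstants:
    """Fixed coefficients of the stoichiometric conversion equations.

    ``fox`` multiplies (O2 L, mCO2 L, urinary N g); ``cox`` multiplies
    (mCO2 L, O2 L, urinary N g) — note the swapped order, matching the
    printed equations; ``hp`` multiplies (O2 L, total CO2 L, CH4 L,
    urinary N g). ``co2_ferm_per_ch4`` converts CH4 volume to fermentative
    CO2 volume.
    """

    co2_ferm_per_ch4: float = 1.7
    fox: tuple[float, float, float] = (1.67, -1.67, -1.92)
    cox: tuple[float, float, float] = (4.55, -3.21, -2.87)
    hp: tuple[float, float, float, float] = (16.18, 5.02, -2.17, -5.99)


#: module-level immutable default coefficient set
CONSTANTS = StoichiometricConstants()


@dataclass
class ChamberTrace:
    """One chamber occupancy: concentration time series plus geometry.

    Parameters
    ----------
    time_h
        Sample times in hours since the start of the occupancy; strictly
        increasing.
    inlet, outlet
        Mapping gas name -> volume-fraction array aligned with ``time_h``.
    airflow_m3_h
        Constant airflow through the chamber.
    recovery
        Gas recovery rate of the chamber measurement system (0, 1];
        integrated volumes are divided by it.
    """

    time_h: np.ndarray
    inlet: dict[str, np.ndarray]
    outlet: dict[str, np.ndarray]
    airflow_m3_h: float
    recovery: float = 1.0
    chamber_id: str = "chamber-1"
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.time_h = np.asarray(self.time_h, dtype=float)
        if self.time_h.ndim != 1 or self.time_h.size < 2:
            raise ValueError("time_h must be a 1-d array with >= 2 samples")
        if not np.all(np.diff(self.time_h) > 0):
            raise ValueError("time_h must be strictly increasing")
        for name, table in (("inlet", self.inlet), ("outlet", self.outlet)):
            for gas in GASES:
                if gas not in table:
                    raise ValueError(f"{name} is missing gas {gas!r}")
                arr = np.asarray(table[gas], dtype=float)
                if arr.shape != self.time_h.shape:
                    raise ValueError(
                        f"{name}[{gas!r}] has shape {arr.shape}, "
                        f"expected {self.time_h.shape}"
                    )
                if np.any((arr < 0) | (arr > 1)):
                    raise ValueError(f"{name}[{gas!r}] outside [0, 1]")
                table[gas] = arr
        if not self.airflow_m3_h > 0:
            raise ValueError("airflow_m3_h must be > 0")
        if not 0 < self.recovery <= 1:
            raise ValueError("recovery must be in (0, 1]")


@dataclass(frozen=True)
class GasVolumes:
    """Daily gas volumes recovered from one integration window."""

    o2_l_d: float
    co2_l_d: float
    ch4_l_d: float
    window_h: float
    flags: tuple[str, ...] = ()

    @property
    def valid(self) -> bool:
        return not any(f.startswith("invalid") for f in self.flags)


def integrate_gas_exchange(
    trace: ChamberTrace,
    window: tuple[float, float],
    max_gap_min: float = 30.0,
    correction: float = 1.0,
) -> GasVolumes:
    """Invert the chamber mass balance over ``window`` (hours).

    Production of CO2/CH4 is the trapezoidal integral of
    ``(C_out - C_in) * Q`` over the window, divided by the recovery rate and
    rescaled to L/d; O2 consumption uses ``(C_in - C_out)``. Partial first
    and last sampling intervals are prorated by linear interpolation of the
    concentration difference at the window edges.

    Gaps longer than ``max_gap_min`` minutes inside the window flag the day
    as invalid (volumes are reported as NaN); negative integrated
    production is flagged but returned as-is.
    """
    t0, t1 = float(window[0]), float(window[1])
    if not t1 > t0:
        raise ValueError("window must satisfy t1 > t0")
    t = trace.time_h
    if t0 < t[0] - 1e-9 or t1 > t[-1] + 1e-9:
        raise ValueError(
            f"window [{t0}, {t1}] h not covered by trace "
            f"[{t[0]}, {t[-1]}] h"
        )
    if correction <= 0:
        raise ValueError("correction must be > 0")

    inside = (t >= t0) & (t <= t1)
    t_in = t[inside]
    # prorate partial boundary intervals
    grid = np.concatenate(([t0], t_in, [t1]))
    grid = np.unique(grid)

    flags: list[str] = []
    gaps = np.diff(grid)
    if gaps.size == 0 or np.max(gaps) > max_gap_min / 60.0:
        flags.append(f"invalid: gap > {max_gap_min:g} min inside window")
        return GasVolumes(np.nan, np.nan, np.nan, t1 - t0, tuple(flags))

    window_h = t1 - t0
    out: dict[str, float] = {}
    for gas in GASES:
        delta = trace.outlet[gas] - trace.inlet[gas]
        if gas == "o2":
            delta = -delta
        dgrid = np.interp(grid, t, delta)
        volume_m3 = np.trapezoid(dgrid, grid) * trace.airflow_m3_h
        volume_m3 /= trace.recovery
        volume_m3 *= correction
        l_per_d = volume_m3 * 1000.0 * 24.0 / window_h
        if l_per_d < 0:
            flags.append(f"negative integrated {gas} ({l_per_d:.3g} L/d)")
        out[gas] = l_per_d
    return GasVolumes(out["o2"], out["co2"], out["ch4"], window_h, tuple(flags))


def fermentative_co2(
    ch4_l: float, constants: StoichiometricConstants = CONSTANTS
) -> float:
    """Fermentative CO2 volume (L) from CH4 volume (L)."""
    if ch4_l < 0:
        raise ValueError("ch4_l must be >= 0")
    return constants.co2_ferm_per_ch4 * ch4_l


def metabolic_co2(
    co2_total_l: float, ch4_l: float, constants: StoichiometricConstants = CONSTANTS
) -> float:
    """Metabolic CO2 (L): total CO2 minus the fermentative share."""
    ferm = fermentative_co2(ch4_l, constants)
    if ferm > co2_total_l:
        raise ValueError(
            f"fermentative CO2 ({ferm:.3g} L) exceeds total CO2 "
            f"({co2_total_l:.3g} L)"
        )
    return co2_total_l - ferm


def metabolic_rq(mco2_l: float, o2_l: float) -> float:
    """Metabolic respiratory quotient mCO2 / O2."""
    if o2_l <= 0:
        raise ValueError("o2_l must be > 0 for a defined quotient")
    if mco2_l < 0:
        raise ValueError("mco2_l must be >= 0")
    return mco2_l / o2_l


def _oxidation(
    name: str,
    coeffs: tuple[float, float, float],
    x1: float,
    x2: float,
    nu_g: float,
) -> float:
    if min(x1, x2, nu_g) < 0:
        raise ValueError(f"{name} inputs must be >= 0")
    value = coeffs[0] * x1 + coeffs[1] * x2 + coeffs[2] * nu_g
    if value < 0:
        warnings.warn(
            f"negative {name} ({value:.3g} g/d): net synthesis regime",
            NegativeOxidationWarning,
            stacklevel=3,
        )
    return value


def fat_oxidation(
    o2_l: float,
    mco2_l: float,
    nu_g: float,
    constants: StoichiometricConstants = CONSTANTS,
) -> float:
    """Net fat oxidation (g/d) from O2, metabolic CO2 and urinary N.

    Negative values are returned unchanged with a
    :class:`NegativeOxidationWarning` (net lipogenesis regime).
    """
    return _oxidation("FOX", constants.fox, o2_l, mco2_l, nu_g)


def carbohydrate_oxidation(
    o2_l: float,
    mco2_l: float,
    nu_g: float,
    constants: StoichiometricConstants = CONSTANTS,
) -> float:
    """Net carbohydrate oxidation (g/d); same conventions as fat_oxidation.

    The leading coefficient multiplies metabolic CO2 (not O2) here.
    """
    return _oxidation("COX", constants.cox, mco2_l, o2_l, nu_g)


def heat_production(
    o2_l: float,
    co2_total_l: float,
    ch4_l: float,
    nu_g: float,
    constants: StoichiometricConstants = CONSTANTS,
) -> float:
    """Heat production (kJ/d) from O2, *total* CO2, CH4 and urinary N.

    Note the convention asymmetry: heat production uses total CO2 while the
    oxidation equations use metabolic CO2.
    """
    if min(o2_l, co2_total_l, ch4_l, nu_g) < 0:
        raise ValueError("heat_production inputs must be >= 0")
    a, b, c, d = constants.hp
    return a * o2_l + b * co2_total_l + c * ch4_l + d * nu_g


@dataclass
class GasExchangeDaily:
    """Daily gas exchange for one cow-day plus everything derived from it."""

    o2_l_d: float
    co2_l_d: float
    ch4_l_d: float
    nu_g_d: float
    co2_ferm_l_d: float = field(init=False)
    mco2_l_d: float = field(init=False)
    mrq: float = field(init=False)
    fox_g_d: float = field(init=False)
    cox_g_d: float = field(init=False)
    hp_kj_d: float = field(init=False)

    def __post_init__(self) -> None:
        if min(self.o2_l_d, self.co2_l_d, self.ch4_l_d, self.nu_g_d) < 0:
            raise ValueError("gas volumes and urinary N must be >= 0")
        self.co2_ferm_l_d = fermentative_co2(self.ch4_l_d)
        self.mco2_l_d = metabolic_co2(self.co2_l_d, self.ch4_l_d)
        self.mrq = metabolic_rq(self.mco2_l_d, self.o2_l_d)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", NegativeOxidationWarning)
            self.fox_g_d = fat_oxidation(self.o2_l_d, self.mco2_l_d, self.nu_g_d)
            self.cox_g_d = carbohydrate_oxidation(
                self.o2_l_d, self.mco2_l_d, self.nu_g_d
            )
        self.hp_kj_d = heat_production(
            self.o2_l_d, self.co2_l_d, self.ch4_l_d, self.nu_g_d
        )

    @property
    def hp_mj_d(self) -> float:
        return self.hp_kj_d / 1000.0


def summarize_day(
    day: GasExchangeDaily,
    dmi_kg: float,
    mbw: float,
    ecm_kg: float | None = None,
) -> dict[str, float]:
    """Normalize daily gas-exchange quantities to intake and metabolic size.

    Returns CH4/DMI (L/kg), HP/DMI (kJ/kg), HP/mBW (kJ/kg^0.75), FOX/mBW
    and COX/mBW (g/kg^0.75) and, when ``ecm_kg`` is given, CH4/ECM (L/kg).
    """
    if dmi_kg <= 0:
        raise ValueError("dmi_kg must be > 0")
    if mbw <= 0:
        raise ValueError("mbw must be > 0")
    out = {
        "ch4_per_dmi_l_kg": day.ch4_l_d / dmi_kg,
        "hp_per_dmi_kj_kg": day.hp_kj_d / dmi_kg,
        "hp_per_mbw_kj_kg075": day.hp_kj_d / mbw,
        "fox_per_mbw_g_kg075": day.fox_g_d / mbw,
        "cox_per_mbw_g_kg075": day.cox_g_d / mbw,
    }
    if ecm_kg is not None:
        if ecm_kg <= 0:
            raise ValueError("ecm_kg must be > 0 when supplied")
        out["ch4_per_ecm_l_kg"] = day.ch4_l_d / ecm_kg
    return out
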