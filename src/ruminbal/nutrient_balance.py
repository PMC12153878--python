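"""Performance, efficiency, digestibility and balance quantities.

Everything here operates per cow-day or per cow-period on plain numbers or
small record types; the heavy lifting of trial-wide bookkeeping lives in
:mod:`ruminbal.io_cli`.

Units: masses kg or g as suffixed, energies MJ, nitrogen g, milk component
concentrations either % (``*_pct``) or g/kg (``*_g_kg``) as named.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MILK_N_DIVISOR",
    "CP_PER_N",
    "ECM_ENERGY_MJ_PER_KG",
    "FeedSpec",
    "AnimalDayRecord",
    "ExcretaDaily",
    "NPartition",
    "BalanceResult",
    "metabolic_bw",
    "ecm",
    "milk_energy",
    "mei",
    "energy_balance",
    "n_partition",
    "nue",
    "eue",
    "apparent_digestibility",
    "period_summary",
]

#: milk protein (g) per g of milk nitrogen
MILK_N_DIVISOR = 6.38
#: crude protein (g) per g of feed nitrogen
CP_PER_N = 6.25
#: default energy content of energy-corrected milk, MJ/kg. The literal
#: printed factor 0.00314 MJ/kg is dimensionally implausible (it would make
#: the milk-energy term negligible); 3.14 MJ/kg is the default and either
#: value can be selected explicitly.
ECM_ENERGY_MJ_PER_KG = 3.14


@dataclass(frozen=True)
class FeedSpec:
    """Composition of one diet on a dry-matter basis."""

    dm_fraction: float
    me_mj_per_kg_dm: float
    ge_j_per_g_dm: float
    cp_g_per_kg_dm: float
    ash_g_per_kg_dm: float
    n_g_per_kg_dm: float | None = None

    def __post_init__(self) -> None:
        for name in (
            "dm_fraction",
            "me_mj_per_kg_dm",
            "ge_j_per_g_dm",
            "cp_g_per_kg_dm",
            "ash_g_per_kg_dm",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 < self.dm_fraction <= 1:
            raise ValueError("dm_fraction must be in (0, 1]")
        if self.ash_g_per_kg_dm >= 1000:
            raise ValueError("ash must be < 1000 g/kg DM")
        if self.n_g_per_kg_dm is None:
            # derive N from crude protein when not measured directly
            object.__setattr__(
                self, "n_g_per_kg_dm", self.cp_g_per_kg_dm / CP_PER_N
            )
        elif self.n_g_per_kg_dm < 0:
            raise ValueError("n_g_per_kg_dm must be >= 0")

    @property
    def om_fraction(self) -> float:
        """Organic matter as a fraction of DM."""
        return 1.0 - self.ash_g_per_kg_dm / 1000.0


@dataclass
class AnimalDayRecord:
    """One cow-day of intake, production and design labels."""

    cow_id: str
    date: str
    treatment: str
    period: int
    block: int
    sequence: str
    dmi_kg_d: float
    bw_kg: float
    milk_kg_d: float
    fat_pct: float
    protein_pct: float
    lactose_pct: float
    water_l_d: float = np.nan
    milk_urea_mg_l: float = np.nan

    def __post_init__(self) -> None:
        if self.dmi_kg_d < 0 or self.milk_kg_d < 0:
            raise ValueError("dmi and milk yield must be >= 0")
        if not self.bw_kg > 0:
            raise ValueError("bw_kg must be > 0")
        for name in ("fat_pct", "protein_pct", "lactose_pct"):
            v = getattr(self, name)
            if not 0 <= v <= 15:
                raise ValueError(f"{name}={v} outside [0, 15] %")


@dataclass
class ExcretaDaily:
    """One cow-day of fecal and urinary excretion."""

    cow_id: str
    date: str
    feces_fresh_kg: float
    feces_dm_fraction: float
    feces_n_g_per_kg_dm: float
    feces_ge_j_per_g_dm: float
    feces_ash_g_per_kg_dm: float
    urine_kg_d: float = np.nan
    urine_n_g_per_kg: float = np.nan

    def __post_init__(self) -> None:
        if not 0 < self.feces_dm_fraction <= 1:
            raise ValueError("feces_dm_fraction must be in (0, 1]")
        for name in (
            "feces_fresh_kg",
            "feces_n_g_per_kg_dm",
            "feces_ge_j_per_g_dm",
            "feces_ash_g_per_kg_dm",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def feces_dm_kg(self) -> float:
        return self.feces_fresh_kg * self.feces_dm_fraction


@dataclass(frozen=True)
class NPartition:
    """Daily nitrogen flows, g/d. ``n_urine_g_d`` is NaN when the urine
    volume is missing (flagged, not an error)."""

    n_intake_g_d: float
    n_feces_g_d: float
    n_milk_g_d: float
    n_urine_g_d: float
    flags: tuple[str, ...] = ()

    @property
    def n_retained_g_d(self) -> float:
        return (
            self.n_intake_g_d - self.n_feces_g_d - self.n_milk_g_d - self.n_urine_g_d
        )


@dataclass
class BalanceResult:
    """Digestibility, N-flow, efficiency and energy balance summary for one
    cow-period collection window."""

    cow_id: str
    treatment: str
    period: int
    n_days: int
    dmi_kg_d: float
    milk_kg_d: float
    bw_kg: float
    mbw: float
    ecm_kg_d: float
    milk_energy_mj_d: float
    mei_mj_d: float
    hp_mj_d: float
    eb_mj_d: float
    eb_factor_mj_per_kg: float
    eue: float
    nue: float
    n_intake_g_d: float
    n_feces_g_d: float
    n_urine_g_d: float
    n_milk_g_d: float
    dig_dm: float
    dig_om: float
    dig_energy: float
    cp_degradability: float
    flags: tuple[str, ...] = ()


def metabolic_bw(bw_kg: float) -> float:
    """Metabolic body weight, kg^0.75."""
    if not bw_kg > 0:
        raise ValueError("bw_kg must be > 0")
    return bw_kg**0.75


def ecm(milk_kg: float, fat_pct: float, protein_pct: float) -> float:
    """Energy-corrected milk yield, kg/d."""
    if min(milk_kg, fat_pct, protein_pct) < 0:
        raise ValueError("ecm inputs must be >= 0")
    return milk_kg * ((0.38 * fat_pct + 0.21 * protein_pct + 1.05) / 3.28)


def milk_energy(
    fat_g_kg: float, protein_g_kg: float, lactose_g_kg: float, milk_kg: float
) -> float:
    """Milk energy output, MJ/d, from component concentrations in g/kg."""
    if min(fat_g_kg, protein_g_kg, lactose_g_kg, milk_kg) < 0:
        raise ValueError("milk_energy inputs must be >= 0")
    per_kg = 0.038 * fat_g_kg + 0.024 * protein_g_kg + 0.017 * lactose_g_kg
    return per_kg * milk_kg


def mei(me_mj_per_kg_dm: float, dmi_kg: float) -> float:
    """Metabolizable energy intake, MJ/d."""
    if min(me_mj_per_kg_dm, dmi_kg) < 0:
        raise ValueError("mei inputs must be >= 0")
    return me_mj_per_kg_dm * dmi_kg


def energy_balance(
    mei_mj: float,
    hp_mj: float,
    ecm_kg: float,
    ecm_energy_mj_per_kg: float = ECM_ENERGY_MJ_PER_KG,
) -> float:
    """Energy balance, MJ/d: intake minus heat minus milk energy.

    ``ecm_energy_mj_per_kg`` defaults to 3.14 MJ/kg; passing the literal
    0.00314 reproduces the alternative (implausible) convention and should
    be surfaced by the caller.
    """
    for v in (mei_mj, hp_mj, ecm_kg, ecm_energy_mj_per_kg):
        if not np.isfinite(v):
            raise ValueError("energy_balance inputs must be finite")
    return mei_mj - hp_mj - ecm_kg * ecm_energy_mj_per_kg


def n_partition(
    feed: FeedSpec,
    dmi_kg: float,
    milk_kg: float,
    protein_pct: float,
    excreta: ExcretaDaily,
) -> NPartition:
    """Daily nitrogen flows from intake, milk and excreta records.

    Urinary N pairs the stored urine N concentration (g/kg fresh urine)
    with the urine mass of the record; a missing volume yields NaN urinary
    N plus a flag rather than an error.
    """
    if min(dmi_kg, milk_kg, protein_pct) < 0:
        raise ValueError("n_partition inputs must be >= 0")
    n_intake = dmi_kg * feed.n_g_per_kg_dm
    n_milk = milk_kg * protein_pct * 10.0 / MILK_N_DIVISOR  # pct -> g/kg
    n_feces = excreta.feces_dm_kg * excreta.feces_n_g_per_kg_dm
    flags: tuple[str, ...] = ()
    if np.isnan(excreta.urine_kg_d) or np.isnan(excreta.urine_n_g_per_kg):
        n_urine = float("nan")
        flags = ("urine volume or N concentration missing: urinary N undefined",)
    else:
        n_urine = excreta.urine_kg_d * excreta.urine_n_g_per_kg
    return NPartition(n_intake, n_feces, n_milk, n_urine, flags)


def nue(n_milk_g: float, n_intake_g: float) -> float:
    """Nitrogen use efficiency: milk N / N intake."""
    if n_intake_g <= 0:
        raise ValueError("n_intake_g must be > 0")
    if n_milk_g < 0:
        raise ValueError("n_milk_g must be >= 0")
    return n_milk_g / n_intake_g


def eue(milk_energy_mj: float, mei_mj: float) -> float:
    """Energy use efficiency: milk energy / ME intake."""
    if mei_mj <= 0:
        raise ValueError("mei_mj must be > 0")
    if milk_energy_mj < 0:
        raise ValueError("milk_energy_mj must be >= 0")
    return milk_energy_mj / mei_mj


def apparent_digestibility(intake: float, fecal_excretion: float) -> float:
    """(intake - fecal excretion) / intake, for any nutrient or energy."""
    if intake <= 0:
        raise ValueError("intake must be > 0")
    if fecal_excretion < 0:
        raise ValueError("fecal_excretion must be >= 0")
    return (intake - fecal_excretion) / intake


def period_summary(
    animal_days: pd.DataFrame,
    excreta: pd.DataFrame,
    feed: FeedSpec,
    urine_n_g_per_kg: float,
    hp_mj_d: float = float("nan"),
    eb_factor_mj_per_kg: float = ECM_ENERGY_MJ_PER_KG,
) -> BalanceResult:
    """Collapse one cow-period collection window into a BalanceResult.

    ``animal_days`` and ``excreta`` carry the per-day records of a single
    cow-period (typically the 4-d collection window); daily means are
    formed first and every per-day operation is then applied to the means.
    ``urine_n_g_per_kg`` is the spot concentration measured before the
    window (NaN if unavailable) and is paired with the mean daily urine
    mass of the window.
    """
    if len(animal_days) == 0:
        raise ValueError("period_summary needs >= 1 valid animal-day record")
    if len(excreta) == 0:
        raise ValueError("period_summary needs >= 1 excreta record")
    cows = set(animal_days["cow_id"])
    if len(cows) != 1:
        raise ValueError(f"records span multiple cows: {sorted(cows)}")

    flags: list[str] = []
    dmi = float(animal_days["dmi_kg_d"].mean())
    milk = float(animal_days["milk_kg_d"].mean())
    bw = float(animal_days["bw_kg"].mean())
    fat_pct = float(animal_days["fat_pct"].mean())
    protein_pct = float(animal_days["protein_pct"].mean())
    lactose_pct = float(animal_days["lactose_pct"].mean())

    feces_dm = float(
        (excreta["feces_fresh_kg"] * excreta["feces_dm_fraction"]).mean()
    )
    feces_n_conc = float(excreta["feces_n_g_per_kg_dm"].mean())
    feces_ge = float(excreta["feces_ge_j_per_g_dm"].mean())
    feces_ash = float(excreta["feces_ash_g_per_kg_dm"].mean())
    urine_kg = float(excreta["urine_kg_d"].mean())

    mbw = metabolic_bw(bw)
    ecm_kg = ecm(milk, fat_pct, protein_pct)
    milk_e = milk_energy(
        fat_pct * 10.0, protein_pct * 10.0, lactose_pct * 10.0, milk
    )
    mei_mj = mei(feed.me_mj_per_kg_dm, dmi)

    n_intake = dmi * feed.n_g_per_kg_dm
    n_milk = milk * protein_pct * 10.0 / MILK_N_DIVISOR
    n_feces = feces_dm * feces_n_conc
    if np.isnan(urine_kg) or np.isnan(urine_n_g_per_kg):
        n_urine = float("nan")
        flags.append("urinary N undefined (missing urine volume or concentration)")
    else:
        n_urine = urine_kg * urine_n_g_per_kg

    dig_dm = apparent_digestibility(dmi, feces_dm)
    om_intake = dmi * feed.om_fraction
    om_fecal = feces_dm * (1.0 - feces_ash / 1000.0)
    dig_om = apparent_digestibility(om_intake, om_fecal)
    ge_intake_mj = dmi * feed.ge_j_per_g_dm / 1000.0  # kg * J/g -> MJ
    ge_fecal_mj = feces_dm * feces_ge / 1000.0
    dig_energy = apparent_digestibility(ge_intake_mj, ge_fecal_mj)
    cp_deg = apparent_digestibility(n_intake, n_feces)

    if np.isfinite(hp_mj_d):
        eb = energy_balance(mei_mj, hp_mj_d, ecm_kg, eb_factor_mj_per_kg)
    else:
        eb = float("nan")
        flags.append("no heat production supplied: EB undefined")
    if abs(eb_factor_mj_per_kg - ECM_ENERGY_MJ_PER_KG) > 1e-12:
        flags.append(
            f"non-default EB milk-energy factor {eb_factor_mj_per_kg} MJ/kg ECM"
        )

    return BalanceResult(
        cow_id=next(iter(cows)),
        treatment=str(animal_days["treatment"].iloc[0]),
        period=int(animal_days["period"].iloc[0]),
        n_days=len(animal_days),
        dmi_kg_d=dmi,
        milk_kg_d=milk,
        bw_kg=bw,
        mbw=mbw,
        ecm_kg_d=ecm_kg,
        milk_energy_mj_d=milk_e,
        mei_mj_d=mei_mj,
        hp_mj_d=hp_mj_d,
        eb_mj_d=eb,
        eb_factor_mj_per_kg=eb_factor_mj_per_kg,
        eue=eue(milk_e, mei_mj) if mei_mj > 0 else float("nan"),
        nue=nue(n_milk, n_intake) if n_intake > 0 else float("nan"),
        n_intake_g_d=n_intake,
        n_feces_g_d=n_feces,
        n_urine_g_d=n_urine,
        n_milk_g_d=n_milk,
        dig_dm=dig_dm,
        dig_om=dig_om,
        dig_energy=dig_energy,
        cp_degradability=cp_deg,
        flags=tuple(flags),
    )
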