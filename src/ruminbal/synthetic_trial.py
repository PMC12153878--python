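"""Synthetic crossover-trial generator with known ground truth.

Builds complete 2x2 crossover datasets — design, cow-day performance
records, chamber gas traces and excreta — from an explicit effect
specification, and stores every latent quantity in a truth table so that
every downstream stage can be verified in closed loop.

Responses follow the additive structure

    y_ij = baseline + treatment + period + block + cow_i + eps_ij

with a cow random intercept and i.i.d. Gaussian residuals. Excreta are
allocated so that, with noise off, digestibilities and nitrogen flows
recomputed downstream equal the configured truths exactly; the nitrogen
ledger closes by construction (intake = feces + urine + milk + retention).

Randomness: one root seed; independent sub-streams are derived per cow and
per chamber trace via ``numpy.random.SeedSequence`` spawning, so identical
inputs regenerate byte-identical datasets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calorimetry import GASES, ChamberTrace
from .nutrient_balance import MILK_N_DIVISOR, FeedSpec

__all__ = [
    "TREATMENTS",
    "SEQUENCES",
    "AMBIENT_FRACTIONS",
    "CrossoverDesign",
    "ResponseEffect",
    "EmissionTruth",
    "DigestibilityTruth",
    "EffectSpec",
    "TrialDataset",
    "make_design",
    "default_feeds",
    "default_effect_spec",
    "simulate_trial",
    "simulate_excreta",
    "simulate_chamber_trace",
]

TREATMENTS = ("HEMP", "CON")
SEQUENCES = ("hemp-soya", "soya-hemp")

#: ambient inlet gas fractions (dry air); CH4 effectively zero
AMBIENT_FRACTIONS = {"o2": 0.2095, "co2": 0.0004, "ch4": 0.0}


def _treatment_for(sequence: str, period: int) -> str:
    first = "HEMP" if sequence == "hemp-soya" else "CON"
    second = "CON" if first == "HEMP" else "HEMP"
    return first if period == 1 else second


@dataclass
class CrossoverDesign:
    """Cow-level design table plus period geometry.

    ``cows`` columns: cow_id, block, sequence. Every block must contain an
    even number of cows split half/half across the two sequences; every cow
    serves both periods with opposite treatments.
    """

    cows: pd.DataFrame
    period_length_d: int = 21
    washout_d: int = 14

    def __post_init__(self) -> None:
        req = {"cow_id", "block", "sequence"}
        missing = req - set(self.cows.columns)
        if missing:
            raise ValueError(f"design table missing columns {sorted(missing)}")
        if self.cows["cow_id"].duplicated().any():
            raise ValueError("duplicate cow_id in design")
        if self.washout_d < 0:
            raise ValueError("washout_d must be >= 0")
        if self.period_length_d <= 0:
            raise ValueError("period_length_d must be > 0")
        bad = set(self.cows["sequence"]) - set(SEQUENCES)
        if bad:
            raise ValueError(f"unknown sequences {sorted(bad)}")
        for block, grp in self.cows.groupby("block"):
            counts = grp["sequence"].value_counts()
            if len(grp) % 2 or counts.get(SEQUENCES[0], 0) != counts.get(
                SEQUENCES[1], 0
            ):
                raise ValueError(
                    f"block {block} not split evenly across sequences"
                )

    @property
    def n_cows(self) -> int:
        return len(self.cows)

    def long(self) -> pd.DataFrame:
        """One row per cow-period with the realized treatment."""
        rows = []
        for _, cow in self.cows.iterrows():
            for period in (1, 2):
                rows.append(
                    {
                        "cow_id": cow["cow_id"],
                        "block": int(cow["block"]),
                        "sequence": cow["sequence"],
                        "period": period,
                        "treatment": _treatment_for(cow["sequence"], period),
                    }
                )
        return pd.DataFrame(rows)


def make_design(
    n_blocks: int = 3,
    cows_per_block: int = 4,
    period_length_d: int = 21,
    washout_d: int = 14,
    seed: int | None = None,
) -> CrossoverDesign:
    """Balanced design: ``cows_per_block`` cows per block, sequences split
    half/half within block (randomized when ``seed`` is given)."""
    if cows_per_block % 2:
        raise ValueError("cows_per_block must be even")
    rng = np.random.default_rng(seed)
    rows = []
    cow_no = 0
    for block in range(1, n_blocks + 1):
        seqs = [SEQUENCES[0]] * (cows_per_block // 2) + [
            SEQUENCES[1]
        ] * (cows_per_block // 2)
        if seed is not None:
            rng.shuffle(seqs)
        for seq in seqs:
            cow_no += 1
            rows.append(
                {"cow_id": f"cow-{cow_no:02d}", "block": block, "sequence": seq}
            )
    return CrossoverDesign(pd.DataFrame(rows), period_length_d, washout_d)


@dataclass(frozen=True)
class ResponseEffect:
    """Additive effect structure for one response."""

    baseline: float
    treatment: float = 0.0  # added for HEMP
    period: float = 0.0  # added in period 2
    block: tuple[float, ...] = (0.0, 0.0, 0.0)
    cow_sd: float = 0.0
    residual_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.cow_sd < 0 or self.residual_sd < 0:
            raise ValueError("SDs must be >= 0")


@dataclass(frozen=True)
class EmissionTruth:
    """True daily gas rates (L/d) for one treatment, with an optional
    24-h sinusoidal diurnal modulation of relative amplitude
    ``diurnal_amplitude``."""

    o2_l_d: float
    co2_l_d: float
    ch4_l_d: float
    diurnal_amplitude: float = 0.10

    def __post_init__(self) -> None:
        if min(self.o2_l_d, self.co2_l_d, self.ch4_l_d) <= 0:
            raise ValueError("emission rates must be > 0")
        if not 0 <= self.diurnal_amplitude < 1:
            raise ValueError("diurnal_amplitude must be in [0, 1)")

    def as_dict(self) -> dict[str, float]:
        return {"o2": self.o2_l_d, "co2": self.co2_l_d, "ch4": self.ch4_l_d}


@dataclass(frozen=True)
class DigestibilityTruth:
    """True apparent digestibilities for one treatment."""

    dig_dm: float
    dig_om: float
    dig_energy: float
    cp_degradability: float

    def __post_init__(self) -> None:
        for name in ("dig_dm", "dig_om", "dig_energy", "cp_degradability"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name}={v} outside [0, 1]")


@dataclass
class EffectSpec:
    """Complete ground-truth specification of a synthetic trial."""

    responses: dict[str, ResponseEffect]
    emissions: dict[str, EmissionTruth]
    digestibility: dict[str, DigestibilityTruth]
    n_retention_g_d: float = 20.0
    urine_kg_d: float = 11.5
    feces_dm_fraction: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        for table, name in (
            (self.emissions, "emissions"),
            (self.digestibility, "digestibility"),
        ):
            missing = set(TREATMENTS) - set(table)
            if missing:
                raise ValueError(f"{name} missing treatments {sorted(missing)}")
        if not 0 < self.feces_dm_fraction <= 1:
            raise ValueError("feces_dm_fraction must be in (0, 1]")
        if self.urine_kg_d <= 0:
            raise ValueError("urine_kg_d must be > 0")


@dataclass
class TrialDataset:
    """Generated trial: per-day records, excreta, truth table, flags."""

    design: CrossoverDesign
    animal_days: pd.DataFrame
    excreta: pd.DataFrame
    truth: pd.DataFrame
    n_truncated: int = 0


def default_feeds() -> dict[str, FeedSpec]:
    """Plausible diet compositions for the two treatments."""
    return {
        "HEMP": FeedSpec(
            dm_fraction=0.4168,
            me_mj_per_kg_dm=11.45,
            ge_j_per_g_dm=18257.0,
            cp_g_per_kg_dm=154.17,
            ash_g_per_kg_dm=72.83,
        ),
        "CON": FeedSpec(
            dm_fraction=0.4201,
            me_mj_per_kg_dm=11.45,
            ge_j_per_g_dm=18647.0,
            cp_g_per_kg_dm=152.17,
            ash_g_per_kg_dm=64.33,
        ),
    }


def default_effect_spec(seed: int = 0) -> EffectSpec:
    """Trial-scale default truth: lactating-cow magnitudes with a small
    treatment contrast on intake and milk."""
    return EffectSpec(
        responses={
            "dmi_kg_d": ResponseEffect(
                17.6, treatment=-0.4, period=0.2, block=(0.0, 0.5, -0.5),
                cow_sd=1.2, residual_sd=0.6,
            ),
            "milk_kg_d": ResponseEffect(
                29.8, treatment=-0.6, period=-0.5, block=(0.0, 1.0, -1.0),
                cow_sd=2.5, residual_sd=1.0,
            ),
            "fat_pct": ResponseEffect(4.1, cow_sd=0.3, residual_sd=0.1),
            "protein_pct": ResponseEffect(3.6, cow_sd=0.2, residual_sd=0.05),
            "lactose_pct": ResponseEffect(4.99, cow_sd=0.05, residual_sd=0.02),
            "bw_kg": ResponseEffect(620.0, cow_sd=35.0, residual_sd=4.0),
            "water_l_d": ResponseEffect(
                80.0, treatment=-4.0, cow_sd=6.0, residual_sd=3.0
            ),
        },
        emissions={
            "HEMP": EmissionTruth(5000.0, 5400.0, 511.0),
            "CON": EmissionTruth(5050.0, 5500.0, 522.0),
        },
        digestibility={
            "HEMP": DigestibilityTruth(0.657, 0.674, 0.651, 0.641),
            "CON": DigestibilityTruth(0.675, 0.689, 0.671, 0.652),
        },
        seed=seed,
    )


_DERIVED_NAN = {
    k: float("nan")
    for k in (
        "n_intake_g_d", "n_feces_g_d", "n_milk_g_d", "n_urine_g_d",
        "ecm_kg_d", "milk_energy_mj_d", "mei_mj_d", "hp_mj_d", "eb_mj_d",
        "nue", "eue",
    )
}


def _derived_truth(
    latent: dict[str, float],
    em: EmissionTruth,
    dig: DigestibilityTruth,
    feed: FeedSpec,
    effects: EffectSpec,
) -> dict[str, float]:
    """Derived ground-truth quantities for one cow-period, computed with
    plain inline arithmetic (deliberately not via the analysis modules, so
    the closure tests compare two independent routes)."""
    needed = ("dmi_kg_d", "milk_kg_d", "fat_pct", "protein_pct", "lactose_pct")
    if any(k not in latent for k in needed):
        return dict(_DERIVED_NAN)
    dmi, milk = latent["dmi_kg_d"], latent["milk_kg_d"]
    fat, prot, lac = latent["fat_pct"], latent["protein_pct"], latent["lactose_pct"]
    n_intake = dmi * feed.n_g_per_kg_dm
    n_milk = milk * prot * 10.0 / MILK_N_DIVISOR
    n_feces = (1.0 - dig.cp_degradability) * n_intake
    n_urine = n_intake - n_feces - n_milk - effects.n_retention_g_d
    ecm_t = milk * ((0.38 * fat + 0.21 * prot + 1.05) / 3.28)
    milk_e = (0.038 * fat * 10 + 0.024 * prot * 10 + 0.017 * lac * 10) * milk
    mei_t = feed.me_mj_per_kg_dm * dmi
    hp_kj = (
        16.18 * em.o2_l_d + 5.02 * em.co2_l_d - 2.17 * em.ch4_l_d
        - 5.99 * n_urine
    )
    return {
        "n_intake_g_d": n_intake,
        "n_feces_g_d": n_feces,
        "n_milk_g_d": n_milk,
        "n_urine_g_d": n_urine,
        "ecm_kg_d": ecm_t,
        "milk_energy_mj_d": milk_e,
        "mei_mj_d": mei_t,
        "hp_mj_d": hp_kj / 1000.0,
        "eb_mj_d": mei_t - hp_kj / 1000.0 - ecm_t * 3.14,
        "nue": n_milk / n_intake if n_intake > 0 else float("nan"),
        "eue": milk_e / mei_t if mei_t > 0 else float("nan"),
    }


def _cow_streams(
    seed: int, cow_ids: list[str], namespace: int
) -> dict[str, np.random.Generator]:
    root = np.random.SeedSequence(entropy=seed, spawn_key=(namespace,))
    children = root.spawn(len(cow_ids))
    return {cid: np.random.default_rng(s) for cid, s in zip(cow_ids, children)}


def simulate_trial(
    design: CrossoverDesign,
    effects: EffectSpec,
    feeds: dict[str, FeedSpec] | None = None,
    days_per_period: int = 4,
    start_day: int = 15,
    include_excreta: bool = True,
) -> TrialDataset:
    """Generate per cow-day performance records plus the truth table.

    ``days_per_period`` days are generated per cow-period starting at
    experimental day ``start_day`` (the collection window). Negative
    generated DMI or milk values are truncated to 0 and counted in
    ``TrialDataset.n_truncated``. ``include_excreta=False`` skips the
    excreta allocation (useful when only the response structure matters,
    e.g. in statistics simulations, where extreme draws could make the
    nitrogen ledger infeasible).
    """
    feeds = feeds if feeds is not None else default_feeds()
    long = design.long()
    cow_ids = list(design.cows["cow_id"])
    streams = _cow_streams(effects.seed, cow_ids, namespace=0)

    # one random intercept per cow per response, drawn in fixed order
    intercepts: dict[str, dict[str, float]] = {}
    for cid in cow_ids:
        rng = streams[cid]
        intercepts[cid] = {
            name: rng.normal(0.0, eff.cow_sd) if eff.cow_sd > 0 else 0.0
            for name, eff in sorted(effects.responses.items())
        }

    n_truncated = 0
    day_rows = []
    truth_rows = []
    for _, occ in long.iterrows():
        cid, period, block = occ["cow_id"], occ["period"], occ["block"]
        treatment, sequence = occ["treatment"], occ["sequence"]
        rng = streams[cid]
        latent = {}
        for name, eff in sorted(effects.responses.items()):
            mu = (
                eff.baseline
                + (eff.treatment if treatment == "HEMP" else 0.0)
                + (eff.period if period == 2 else 0.0)
                + eff.block[block - 1]
                + intercepts[cid][name]
            )
            latent[name] = mu
        em = effects.emissions[treatment]
        dig = effects.digestibility[treatment]
        truth_row = {
            "cow_id": cid,
            "period": period,
            "treatment": treatment,
            "sequence": sequence,
            "block": block,
            **{f"latent_{k}": v for k, v in latent.items()},
            "o2_l_d": em.o2_l_d,
            "co2_l_d": em.co2_l_d,
            "ch4_l_d": em.ch4_l_d,
            "dig_dm": dig.dig_dm,
            "dig_om": dig.dig_om,
            "dig_energy": dig.dig_energy,
            "cp_degradability": dig.cp_degradability,
            "urine_kg_d": effects.urine_kg_d,
            "n_retention_g_d": effects.n_retention_g_d,
        }
        truth_row.update(
            _derived_truth(latent, em, dig, feeds[treatment], effects)
        )
        truth_rows.append(truth_row)
        for d in range(days_per_period):
            row = {
                "cow_id": cid,
                "period": period,
                "day": start_day + d,
                "treatment": treatment,
                "sequence": sequence,
                "block": block,
            }
            for name, eff in sorted(effects.responses.items()):
                value = latent[name]
                if eff.residual_sd > 0:
                    value += rng.normal(0.0, eff.residual_sd)
                if name in ("dmi_kg_d", "milk_kg_d") and value < 0:
                    value = 0.0
                    n_truncated += 1
                row[name] = value
            day_rows.append(row)

    animal_days = pd.DataFrame(day_rows)
    truth = pd.DataFrame(truth_rows)
    if include_excreta:
        excreta = simulate_excreta(animal_days, effects, feeds)
    else:
        excreta = pd.DataFrame()
    return TrialDataset(design, animal_days, excreta, truth, n_truncated)


def simulate_excreta(
    animal_days: pd.DataFrame,
    effects: EffectSpec,
    feeds: dict[str, FeedSpec],
    noise_cv: float = 0.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Allocate fecal and urinary excretion so the configured truths hold.

    Fecal DM, OM, energy and N are back-computed from the digestibility
    truths applied to each day's realized intake; urinary N closes the
    nitrogen ledger given milk N and the configured retention. With
    ``noise_cv`` = 0 the allocation is exact; otherwise multiplicative
    lognormal-free Gaussian noise of that CV perturbs the fecal fresh mass
    and urine concentration (composition kept consistent).

    Raises ``ValueError`` when the ledger is infeasible (negative implied
    urinary N) naming the offending cow-day.
    """
    rng = np.random.default_rng(seed if seed is not None else effects.seed + 10_000)
    rows = []
    for _, day in animal_days.iterrows():
        treatment = day["treatment"]
        feed = feeds[treatment]
        dig = effects.digestibility[treatment]
        dmi = float(day["dmi_kg_d"])
        milk = float(day["milk_kg_d"])

        feces_dm = (1.0 - dig.dig_dm) * dmi
        om_intake = dmi * feed.om_fraction
        feces_om = (1.0 - dig.dig_om) * om_intake
        if feces_om > feces_dm + 1e-12:
            raise ValueError(
                f"infeasible digestibility truths for {day['cow_id']} "
                f"period {day['period']} day {day['day']}: fecal OM "
                f"{feces_om:.3f} kg exceeds fecal DM {feces_dm:.3f} kg"
            )
        n_intake = dmi * feed.n_g_per_kg_dm
        n_feces = (1.0 - dig.cp_degradability) * n_intake
        n_milk = milk * float(day["protein_pct"]) * 10.0 / MILK_N_DIVISOR
        n_urine = n_intake - n_feces - n_milk - effects.n_retention_g_d
        if n_urine < 0:
            raise ValueError(
                f"nitrogen ledger infeasible for {day['cow_id']} period "
                f"{day['period']} day {day['day']}: implied urinary N "
                f"{n_urine:.1f} g/d < 0 (intake {n_intake:.1f}, feces "
                f"{n_feces:.1f}, milk {n_milk:.1f}, retention "
                f"{effects.n_retention_g_d:.1f})"
            )
        ge_intake_mj = dmi * feed.ge_j_per_g_dm / 1000.0
        ge_fecal_mj = (1.0 - dig.dig_energy) * ge_intake_mj

        if feces_dm > 0:
            feces_n_conc = n_feces / feces_dm
            feces_ge = ge_fecal_mj * 1000.0 / feces_dm  # J/g DM
            feces_ash = 1000.0 * (feces_dm - feces_om) / feces_dm
        else:
            feces_n_conc = feces_ge = feces_ash = 0.0
        urine_kg = effects.urine_kg_d
        urine_n_conc = n_urine / urine_kg
        feces_fresh = feces_dm / effects.feces_dm_fraction

        if noise_cv > 0:
            feces_fresh *= max(0.0, 1.0 + rng.normal(0.0, noise_cv))
            urine_n_conc *= max(0.0, 1.0 + rng.normal(0.0, noise_cv))

        rows.append(
            {
                "cow_id": day["cow_id"],
                "period": day["period"],
                "day": day["day"],
                "feces_fresh_kg": feces_fresh,
                "feces_dm_fraction": effects.feces_dm_fraction,
                "feces_n_g_per_kg_dm": feces_n_conc,
                "feces_ge_j_per_g_dm": feces_ge,
                "feces_ash_g_per_kg_dm": feces_ash,
                "urine_kg_d": urine_kg,
                "urine_n_g_per_kg": urine_n_conc,
            }
        )
    return pd.DataFrame(rows)


def simulate_chamber_trace(
    emission_l_d: dict[str, float],
    chamber_volume_m3: float = 50.0,
    airflow_m3_h: float = 30.0,
    inlet_fractions: dict[str, float] | None = None,
    sample_interval_min: float = 6.0,
    duration_h: float = 48.0,
    diurnal_amplitude: float = 0.0,
    noise_sd: dict[str, float] | None | str = "default",
    recovery: float = 1.0,
    seed: int | None = None,
    init: str = "inlet",
    chamber_id: str = "chamber-1",
) -> ChamberTrace:
    """Simulate a well-mixed chamber concentration trace.

    The outlet fraction follows ``V dC/dt = Q C_in + E(t) - Q C_out`` with
    consumption (O2) entering as negative ``E``; the update is the exact
    solution for the piecewise-constant emission over each sampling step.
    ``E(t)`` is the daily rate modulated by an optional 24-h sinusoid.

    The *reported* outlet is the true outlet with its excess over inlet
    scaled by ``recovery`` and perturbed by Gaussian noise (default SD: 1%
    of each gas's steady-state excess). Negative reported concentrations
    are clipped to 0 and flagged. ``init`` selects the initial condition:
    ``"inlet"`` (C(0) = C_in, washout transient) or ``"steady"``.
    """
    if chamber_volume_m3 <= 0 or airflow_m3_h <= 0:
        raise ValueError("chamber volume and airflow must be > 0")
    if not 0 < recovery <= 1:
        raise ValueError("recovery must be in (0, 1]")
    if init not in ("inlet", "steady"):
        raise ValueError("init must be 'inlet' or 'steady'")
    inlet = dict(AMBIENT_FRACTIONS if inlet_fractions is None else inlet_fractions)
    for gas in GASES:
        if gas not in emission_l_d:
            raise ValueError(f"emission_l_d missing gas {gas!r}")

    n_steps = int(round(duration_h * 60.0 / sample_interval_min))
    t = np.arange(n_steps + 1) * sample_interval_min / 60.0  # hours
    dt = sample_interval_min / 60.0
    decay = np.exp(-airflow_m3_h * dt / chamber_volume_m3)

    rng = np.random.default_rng(seed)
    outlet = {}
    flags: list[str] = []
    n_clipped = 0
    for gas in GASES:
        rate_l_d = emission_l_d[gas]
        sign = -1.0 if gas == "o2" else 1.0
        e_mean = sign * rate_l_d / 1000.0 / 24.0  # m3/h
        # emission at step midpoints, optional diurnal sinusoid
        mid = t[:-1] + dt / 2.0
        e_t = e_mean * (1.0 + diurnal_amplitude * np.sin(2.0 * np.pi * mid / 24.0))
        c_ss = inlet[gas] + e_t / airflow_m3_h
        c = np.empty(n_steps + 1)
        c[0] = inlet[gas] if init == "inlet" else inlet[gas] + e_mean / airflow_m3_h
        for k in range(n_steps):
            c[k + 1] = c_ss[k] + (c[k] - c_ss[k]) * decay
        reported = inlet[gas] + recovery * (c - inlet[gas])
        if noise_sd is not None:
            if noise_sd == "default":
                sd = 0.01 * abs(e_mean) / airflow_m3_h
            else:
                sd = noise_sd.get(gas, 0.0)
            if sd > 0:
                reported = reported + rng.normal(0.0, sd, size=reported.shape)
        neg = reported < 0
        if neg.any():
            n_clipped += int(neg.sum())
            reported = np.clip(reported, 0.0, None)
        outlet[gas] = reported
    if n_clipped:
        flags.append(f"{n_clipped} negative reported concentrations clipped to 0")

    inlet_series = {gas: np.full(n_steps + 1, inlet[gas]) for gas in GASES}
    return ChamberTrace(
        time_h=t,
        inlet=inlet_series,
        outlet=outlet,
        airflow_m3_h=airflow_m3_h,
        recovery=recovery,
        chamber_id=chamber_id,
        flags=tuple(flags),
    )
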