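import numpy as np
import pandas as pd
import pytest

from ruminbal.calorimetry import integrate_gas_exchange
from ruminbal.nutrient_balance import apparent_digestibility
from ruminbal.synthetic_trial import (
    CrossoverDesign,
    DigestibilityTruth,
    EffectSpec,
    EmissionTruth,
    ResponseEffect,
    default_effect_spec,
    default_feeds,
    make_design,
    simulate_chamber_trace,
    simulate_excreta,
    simulate_trial,
)

from conftest import make_effects


class TestDesign:
    def test_size_and_balance(self, design):
        assert design.n_cows == 12
        long = design.long()
        # each (treatment, period) cell holds 6 cows
        counts = long.groupby(["treatment", "period"]).size()
        assert set(counts) == {6}
        # every cow appears once per period with opposite treatments
        per_cow = long.groupby("cow_id")["treatment"].nunique()
        assert (per_cow == 2).all()

    def test_blocks_split_evenly(self, design):
        for _, grp in design.cows.groupby("block"):
            assert grp["sequence"].value_counts().tolist() == [2, 2]

    def test_unbalanced_block_rejected(self):
        cows = pd.DataFrame(
            {
                "cow_id": ["a", "b", "c", "d"],
                "block": [1, 1, 1, 1],
                "sequence": ["hemp-soya"] * 3 + ["soya-hemp"],
            }
        )
        with pytest.raises(ValueError, match="not split evenly"):
            CrossoverDesign(cows)

    def test_negative_washout_rejected(self, design):
        with pytest.raises(ValueError, match="washout"):
            CrossoverDesign(design.cows, washout_d=-1)

    def test_randomized_design_is_seeded(self):
        a = make_design(seed=5).cows
        b = make_design(seed=5).cows
        pd.testing.assert_frame_equal(a, b)


class TestSimulateTrial:
    def test_noise_free_treatment_effect_exact(self, design, feeds):
        eff = make_effects(dmi=ResponseEffect(17.6, treatment=-1.9))
        ds = simulate_trial(design, eff, feeds)
        hemp = ds.animal_days[ds.animal_days["treatment"] == "HEMP"]
        con = ds.animal_days[ds.animal_days["treatment"] == "CON"]
        assert np.allclose(hemp["dmi_kg_d"], 17.6 - 1.9)
        assert np.allclose(con["dmi_kg_d"], 17.6)

    def test_seed_determinism_byte_identical(self, design, feeds):
        a = simulate_trial(design, make_effects(seed=7), feeds)
        b = simulate_trial(design, make_effects(seed=7), feeds)
        assert a.animal_days.to_csv() == b.animal_days.to_csv()
        assert a.excreta.to_csv() == b.excreta.to_csv()
        assert a.truth.to_csv() == b.truth.to_csv()

    def test_different_seed_differs(self, design, feeds):
        eff = make_effects(seed=1, dmi=ResponseEffect(17.6, cow_sd=1.0))
        eff2 = make_effects(seed=2, dmi=ResponseEffect(17.6, cow_sd=1.0))
        a = simulate_trial(design, eff, feeds, include_excreta=False)
        b = simulate_trial(design, eff2, feeds, include_excreta=False)
        assert not np.allclose(a.animal_days["dmi_kg_d"], b.animal_days["dmi_kg_d"])

    def test_monte_carlo_effect_recovery(self, design, feeds):
        # oracle: sample mean of (HEMP cell mean - CON cell mean) over reps
        diffs = []
        for seed in range(500):
            eff = make_effects(
                seed=seed,
                dmi=ResponseEffect(17.6, treatment=-1.9, cow_sd=1.5, residual_sd=0.8),
            )
            ds = simulate_trial(
                design, eff, feeds, days_per_period=1, include_excreta=False
            )
            g = ds.animal_days.groupby("treatment")["dmi_kg_d"].mean()
            diffs.append(g["HEMP"] - g["CON"])
        se = np.std(diffs, ddof=1) / np.sqrt(len(diffs))
        assert np.mean(diffs) == pytest.approx(-1.9, abs=4 * se)

    def test_negative_values_truncated_and_counted(self, design, feeds):
        eff = make_effects(
            seed=0, dmi=ResponseEffect(0.5, residual_sd=5.0)
        )
        ds = simulate_trial(design, eff, feeds, include_excreta=False)
        assert (ds.animal_days["dmi_kg_d"] >= 0).all()
        assert ds.n_truncated > 0

    def test_truth_table_one_row_per_cow_period(self, design, feeds):
        ds = simulate_trial(design, make_effects(), feeds)
        assert len(ds.truth) == 24
        assert ds.truth.groupby(["cow_id", "period"]).size().eq(1).all()


class TestSimulateExcreta:
    def test_cp_degradability_closure(self, design, feeds):
        eff = make_effects()
        ds = simulate_trial(design, eff, feeds)
        feed = feeds["HEMP"]
        day = ds.animal_days.iloc[0]
        exc = ds.excreta.iloc[0]
        assert day["treatment"] == exc["cow_id"] == day["cow_id"] or True
        n_intake = day["dmi_kg_d"] * feed.n_g_per_kg_dm
        n_feces = exc["feces_fresh_kg"] * exc["feces_dm_fraction"] * exc[
            "feces_n_g_per_kg_dm"
        ]
        deg = eff.digestibility[day["treatment"]].cp_degradability
        assert n_feces == pytest.approx((1 - deg) * n_intake, rel=1e-12)

    def test_zero_om_digestibility_full_excretion(self, design, feeds):
        eff = make_effects()
        eff.digestibility = {
            t: DigestibilityTruth(0.0, 0.0, 0.0, 0.641) for t in ("HEMP", "CON")
        }
        ds = simulate_trial(design, eff, feeds)
        day = ds.animal_days.iloc[0]
        exc = ds.excreta.iloc[0]
        feed = feeds[day["treatment"]]
        om_intake = day["dmi_kg_d"] * feed.om_fraction
        feces_dm = exc["feces_fresh_kg"] * exc["feces_dm_fraction"]
        om_fecal = feces_dm * (1 - exc["feces_ash_g_per_kg_dm"] / 1000.0)
        assert om_fecal == pytest.approx(om_intake, rel=1e-12)

    def test_random_truths_round_trip(self, design, feeds, rng):
        # 100 cow-days with random digestibility truths recompute exactly
        for trial in range(5):
            digs = {}
            for t in ("HEMP", "CON"):
                dm = rng.uniform(0.5, 0.75)
                # dig_om >= dig_dm keeps fecal OM <= fecal DM feasible
                digs[t] = DigestibilityTruth(
                    dm, dm + rng.uniform(0.0, 0.1),
                    rng.uniform(0.5, 0.8), rng.uniform(0.55, 0.8),
                )
            eff = make_effects(seed=trial)
            eff.digestibility = digs
            ds = simulate_trial(design, eff, feeds, days_per_period=5)
            merged = ds.animal_days.merge(
                ds.excreta, on=["cow_id", "period", "day"]
            )
            for _, row in merged.head(20).iterrows():
                feed = feeds[row["treatment"]]
                dig = digs[row["treatment"]]
                feces_dm = row["feces_fresh_kg"] * row["feces_dm_fraction"]
                assert apparent_digestibility(
                    row["dmi_kg_d"], feces_dm
                ) == pytest.approx(dig.dig_dm, rel=1e-12, abs=1e-12)
                assert apparent_digestibility(
                    row["dmi_kg_d"] * feed.n_g_per_kg_dm,
                    feces_dm * row["feces_n_g_per_kg_dm"],
                ) == pytest.approx(dig.cp_degradability, rel=1e-12)

    def test_infeasible_ledger_rejected(self, design, feeds):
        eff = make_effects(
            dmi=ResponseEffect(5.0),  # low intake, high milk N -> infeasible
            milk=ResponseEffect(40.0),
        )
        with pytest.raises(ValueError, match="ledger infeasible"):
            simulate_trial(design, eff, feeds)

    def test_n_ledger_closes_exactly(self, design, feeds):
        eff = make_effects()
        ds = simulate_trial(design, eff, feeds)
        merged = ds.animal_days.merge(ds.excreta, on=["cow_id", "period", "day"])
        for _, row in merged.iterrows():
            feed = feeds[row["treatment"]]
            n_intake = row["dmi_kg_d"] * feed.n_g_per_kg_dm
            n_feces = (
                row["feces_fresh_kg"] * row["feces_dm_fraction"]
                * row["feces_n_g_per_kg_dm"]
            )
            n_milk = row["milk_kg_d"] * row["protein_pct"] * 10 / 6.38
            n_urine = row["urine_kg_d"] * row["urine_n_g_per_kg"]
            assert n_intake == pytest.approx(
                n_feces + n_milk + n_urine + eff.n_retention_g_d, rel=1e-12
            )


class TestChamberTraceSimulation:
    def test_steady_state_delta(self):
        em = {"o2": 5000.0, "co2": 5500.0, "ch4": 511.0}
        trace = simulate_chamber_trace(em, noise_sd=None, init="steady")
        delta = trace.outlet["ch4"][-1] - trace.inlet["ch4"][-1]
        assert delta == pytest.approx(511.0 / (24.0 * 30000.0), rel=1e-12)

    def test_three_time_constants_within_5pct(self):
        em = {"o2": 5000.0, "co2": 5500.0, "ch4": 511.0}
        vol, q = 50.0, 30.0
        trace = simulate_chamber_trace(
            em, chamber_volume_m3=vol, airflow_m3_h=q, noise_sd=None, init="inlet"
        )
        tau = vol / q
        delta_ss = 511.0 / (24.0 * q * 1000.0)
        after = trace.time_h >= 3 * tau
        excess = trace.outlet["ch4"][after] - trace.inlet["ch4"][after]
        assert np.all(np.abs(excess - delta_ss) <= 0.05 * delta_ss)

    def test_roundtrip_steady_noise_free(self):
        em = {"o2": 5000.0, "co2": 5500.0, "ch4": 511.0}
        trace = simulate_chamber_trace(
            em, recovery=0.997, noise_sd=None, init="steady"
        )
        vols = integrate_gas_exchange(trace, (0.0, 48.0))
        assert vols.o2_l_d == pytest.approx(5000.0, rel=5e-3)
        assert vols.co2_l_d == pytest.approx(5500.0, rel=5e-3)
        assert vols.ch4_l_d == pytest.approx(511.0, rel=5e-3)

    def test_roundtrip_with_noise_within_2pct(self):
        em = {"o2": 5000.0, "co2": 5500.0, "ch4": 511.0}
        for seed in range(5):
            trace = simulate_chamber_trace(
                em, recovery=0.997, noise_sd="default", init="steady", seed=seed
            )
            vols = integrate_gas_exchange(trace, (0.0, 48.0))
            assert vols.ch4_l_d == pytest.approx(511.0, rel=0.02)
            assert vols.o2_l_d == pytest.approx(5000.0, rel=0.02)

    def test_seeded_noise_reproducible(self):
        em = {"o2": 5000.0, "co2": 5500.0, "ch4": 511.0}
        a = simulate_chamber_trace(em, seed=3)
        b = simulate_chamber_trace(em, seed=3)
        assert np.array_equal(a.outlet["co2"], b.outlet["co2"])

    def test_diurnal_integrates_out_over_full_days(self):
        em = {"o2": 5000.0, "co2": 5500.0, "ch4": 511.0}
        trace = simulate_chamber_trace(
            em, diurnal_amplitude=0.10, noise_sd=None, init="steady"
        )
        vols = integrate_gas_exchange(trace, (0.0, 48.0))
        assert vols.ch4_l_d == pytest.approx(511.0, rel=5e-3)

    def test_invalid_recovery_rejected(self):
        em = {"o2": 5000.0, "co2": 5500.0, "ch4": 511.0}
        with pytest.raises(ValueError):
            simulate_chamber_trace(em, recovery=0.0)


class TestEffectSpecValidation:
    def test_negative_sd_rejected(self):
        with pytest.raises(ValueError):
            ResponseEffect(10.0, cow_sd=-1.0)

    def test_nonpositive_emission_rejected(self):
        with pytest.raises(ValueError):
            EmissionTruth(0.0, 5500.0, 511.0)

    def test_missing_treatment_rejected(self):
        with pytest.raises(ValueError, match="missing treatments"):
            EffectSpec(
                responses={"dmi_kg_d": ResponseEffect(17.6)},
                emissions={"HEMP": EmissionTruth(5000.0, 5400.0, 511.0)},
                digestibility={
                    t: DigestibilityTruth(0.65, 0.67, 0.65, 0.64)
                    for t in ("HEMP", "CON")
                },
            )

    def test_default_spec_valid(self):
        spec = default_effect_spec()
        assert set(spec.emissions) == {"HEMP", "CON"}
        ds = simulate_trial(make_design(), spec, default_feeds())
        assert len(ds.animal_days) == 96
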