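import numpy as np
import pytest

from ruminbal.nutrient_balance import FeedSpec
from ruminbal.synthetic_trial import (
    DigestibilityTruth,
    EffectSpec,
    EmissionTruth,
    ResponseEffect,
    make_design,
)


@pytest.fixture
def design():
    return make_design(n_blocks=3, cows_per_block=4)


@pytest.fixture
def feeds():
    return {
        "HEMP": FeedSpec(
            dm_fraction=0.42, me_mj_per_kg_dm=11.45, ge_j_per_g_dm=18257.0,
            cp_g_per_kg_dm=154.17, ash_g_per_kg_dm=72.83,
        ),
        "CON": FeedSpec(
            dm_fraction=0.42, me_mj_per_kg_dm=11.45, ge_j_per_g_dm=18647.0,
            cp_g_per_kg_dm=152.17, ash_g_per_kg_dm=64.33,
        ),
    }


def make_effects(
    seed=0,
    dmi=ResponseEffect(17.6),
    milk=ResponseEffect(29.8),
    **overrides,
):
    """EffectSpec with trial-scale defaults; noise off unless configured."""
    responses = {
        "dmi_kg_d": dmi,
        "milk_kg_d": milk,
        "fat_pct": ResponseEffect(4.1),
        "protein_pct": ResponseEffect(3.6),
        "lactose_pct": ResponseEffect(4.99),
        "bw_kg": ResponseEffect(620.0),
    }
    responses.update(overrides.pop("responses", {}))
    return EffectSpec(
        responses=responses,
        emissions={
            "HEMP": EmissionTruth(5000.0, 5400.0, 511.0, diurnal_amplitude=0.0),
            "CON": EmissionTruth(5050.0, 5500.0, 522.0, diurnal_amplitude=0.0),
        },
        digestibility={
            "HEMP": DigestibilityTruth(0.657, 0.674, 0.651, 0.641),
            "CON": DigestibilityTruth(0.675, 0.689, 0.671, 0.652),
        },
        seed=seed,
        **overrides,
    )


@pytest.fixture
def effects_noise_free():
    return make_effects()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
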