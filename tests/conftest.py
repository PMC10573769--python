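import numpy as np
import pytest

from chronodose import DoseEvent, builtin_labels, builtin_params, simulate_pk

ALL_LABELS = [
    "passive_diffusion",
    "carrier_amine",
    "carrier_neutral_amino_acid",
    "carrier_t3",
    "nanoparticle",
]

#: single published validation dose (mg) per transport system
VALIDATION_DOSE = {
    "passive_diffusion": 2.0,
    "carrier_amine": 550.0,
    "carrier_neutral_amino_acid": 100.0,
    "carrier_t3": 0.05,
    "nanoparticle": 2.0,
}


@pytest.fixture(scope="session")
def params_table():
    return {label: builtin_params(label) for label in builtin_labels()}


@pytest.fixture(params=ALL_LABELS)
def any_params(request, params_table):
    return params_table[request.param]


@pytest.fixture(scope="session")
def passive(params_table):
    return params_table["passive_diffusion"]


def single_dose_traj(params, dose, horizon=720.0, step=5.0):
    return simulate_pk(params, [DoseEvent(0.0, dose)], horizon=horizon, step=step)
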