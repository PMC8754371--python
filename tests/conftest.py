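import numpy as np
import pandas as pd
import pytest

import ieegface as f
from ieegface import preprocess as pp


@pytest.fixture(scope="session")
def small_design():
    return f.build_trial_design(1, rng_seed=11)


@pytest.fixture(scope="session")
def sim_recording(small_design):
    cfg = f.default_config(rng_seed=7)
    rec, truth = f.simulate_patient_recording(cfg, small_design)
    return rec, truth


@pytest.fixture(scope="session")
def pipeline_outputs(small_design, sim_recording):
    """Full preprocessing chain on one simulated session."""
    rec, truth = sim_recording
    responses = f.simulate_responses(small_design, rng_seed=8)
    epoch_sets, sites, log = pp.preprocess_pipeline(
        rec, small_design, responses=responses, blink_channel="SCALP1")
    return epoch_sets, sites, log, truth


def make_flat_recording(design, rate=400.0, n_contacts=4, value=0.0):
    """Constant-signal recording spanning a design (for rejection tests)."""
    from ieegface.design import design_duration_s
    n_samples = int(np.ceil(design_duration_s(design) * rate))
    contacts = pd.DataFrame([{
        "channel": f"A{k+1}", "shaft": "A", "index": k + 1,
        "label": "fusiform gyrus", "x": 30.0 + 5 * k, "y": -50.0,
        "z": -20.0, "in_brain": True, "excluded": False, "is_blink": False}
        for k in range(n_contacts)])
    signal = np.full((n_contacts, n_samples), value)
    return f.ContactRecording(signal=signal, rate=rate, contacts=contacts)
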