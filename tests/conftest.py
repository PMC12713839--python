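import numpy as np
import pytest

from somnoscope import simulate as sim
from somnoscope import staging


@pytest.fixture(scope="session")
def preset_day():
    """One simulated wild-type day: truth hypnogram, signals, staged result.

    Session-scoped because signal synthesis and staging of a full 24-h
    record are the most expensive steps in the suite.
    """
    kin, _ = sim.genotype_presets()["WT"]
    truth = sim.simulate_hypnogram(kin, days=1, seed=42)
    record = sim.synthesize_signals(truth, sim.preset_recipe(), seed=7,
                                    n_eeg=1, n_emg=1)
    staged = staging.stage_record(record)
    return truth, record, staged


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
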