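import numpy as np
import pytest

import neurofatigue as nf
from neurofatigue.pipeline_cli import analyze_experiment, summarize_analysis


@pytest.fixture(scope="session")
def full_experiment():
    """The full study-sized simulation: 11 subjects × 20 sets × 8 reps."""
    cfg = nf.ProtocolConfig(seed=1)
    return nf.generate_protocol(cfg)


@pytest.fixture(scope="session")
def full_summary(full_experiment):
    """Analysis summary of the full simulation (shared across tests)."""
    res = analyze_experiment(full_experiment)
    summary = summarize_analysis(res, full_experiment.config,
                                 full_experiment.vo2, full_experiment.lactate)
    return summary


@pytest.fixture(scope="session")
def noise_free_experiment():
    """A small protocol with every noise source switched off."""
    cfg = nf.ProtocolConfig(
        n_subjects=2, n_sets=3, reps_per_set=2, seed=9,
        noise_levels={k: 0.0 for k in ("torque", "velocity", "imvc", "evoked",
                                       "mwave", "emg_floor", "vo2")})
    return nf.generate_protocol(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
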