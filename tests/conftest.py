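import numpy as np
import pytest

from ephysopt import GroundTruth, SimConfig, StepProtocol, simulate_current_clamp
from ephysopt.synth import NetworkGT, SynapseGT, UnitGT


@pytest.fixture(scope="session")
def step_protocol():
    return StepProtocol()


@pytest.fixture(scope="session")
def default_cc(step_protocol):
    """One default synthetic cell's step family plus its manifest."""
    gt = GroundTruth()
    sweeps, info = simulate_current_clamp(gt, step_protocol, SimConfig(seed=1))
    return gt, sweeps, info


def sweep_at(sweeps, amp_pa):
    return next(s for s in sweeps if s.meta["step_pa"] == amp_pa)


@pytest.fixture
def quiet_synapse():
    """Evoked-only synapse: no spontaneous events, no trial variability."""
    return SynapseGT(event_rate_hz=0.0, trial_cv=0.0)


def oscillation_only_network(**kw):
    """Extracellular ground truth with only band oscillations (no 1/f
    background, no evoked transient, no units) unless overridden."""
    base = dict(band_amplitudes={(4.0, 12.0): 20.0, (12.0, 30.0): 10.0,
                                 (30.0, 45.0): 6.0},
                band_gains={}, background_rms_uv=0.0, evoked_peak_uv=0.0,
                units=())
    base.update(kw)
    return NetworkGT(**base)
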