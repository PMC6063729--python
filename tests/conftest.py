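import numpy as np
import pytest

from lso_ephys import synth
from lso_ephys.core_io import ToneStimulus

FS = 50_000.0


@pytest.fixture(scope="session")
def ipsi_stim():
    return ToneStimulus(
        ear="ipsi", frequency=8_000.0, duration=70.0, level_ipsi=70.0, n_reps=30
    )


@pytest.fixture(scope="session")
def onset_tone_sweeps(ipsi_stim):
    """Principal (onset-firing) responses to an ipsilateral tone."""
    return synth.gen_tone_response(synth.principal_params(), ipsi_stim, seed=3)


@pytest.fixture(scope="session")
def chopper_tone_sweeps(ipsi_stim):
    """Non-principal (chopper) responses to an ipsilateral tone, 50 reps."""
    stim = ToneStimulus(
        ear="ipsi", frequency=8_000.0, duration=70.0, level_ipsi=70.0, n_reps=50
    )
    params = synth.non_principal_params()
    return synth.gen_tone_response(params, stim, seed=4), params


@pytest.fixture(scope="session")
def small_cohort():
    """4 + 4 cells with spontaneous and ipsi-tone protocols."""
    return synth.gen_cohort(
        4, 4, seed=11, include_protocols=("spontaneous", "ipsi_tone")
    )


def make_sweep(samples, fs=FS, **kw):
    from lso_ephys.core_io import Sweep

    return Sweep(samples=np.asarray(samples, dtype=float), sampling_rate=fs, **kw)
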