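import numpy as np
import pytest

from groomsyntax import synthetic as syn
from groomsyntax.ethogram import denoise


@pytest.fixture(scope="session")
def dust_cohort():
    """Two small groups from one shared dust template (null cohort)."""
    tpl = syn.GroupTemplate("shared", syn.dust_base_config(recording_frames=6000))
    flies = syn.simulate_population(tpl, 12, seed=202)
    return [denoise(e) for e in flies]


@pytest.fixture(scope="session")
def opto_session():
    cfg = syn.opto_config(recording_frames=45_000)
    return denoise(syn.simulate_opto_session(cfg, seed=77, fly_id="opto_f00"))
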