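import numpy as np
import pytest

try:
    from hypothesis import HealthCheck, settings

    settings.register_profile(
        "deterministic", derandomize=True, max_examples=25,
        suppress_health_check=[HealthCheck.too_slow])
    settings.load_profile("deterministic")
except ImportError:  # pragma: no cover
    pass

from ratvar import BeatSpec, simulate_beat_series


@pytest.fixture
def shr_spec() -> BeatSpec:
    """An SHR-like beat spec: ~385 bpm with LF/HF oscillations and noise."""
    return BeatSpec(mean_pi=155.92, lf_freq=0.45, lf_amp=3.2, hf_freq=2.4,
                    hf_amp=5.4, noise_sd=7.0, sap_mean=178.43,
                    dap_mean=141.17, sap_lf_amp=6.1, sap_hf_amp=3.1,
                    sap_noise_sd=6.7, n_beats=1000, seed=11)


@pytest.fixture
def shr_beats(shr_spec):
    return simulate_beat_series(shr_spec)
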