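import numpy as np
import pytest

from scgcti.synth import SynthConfig, generate_record

TRUE_LATENCIES = {"MC": 30.0, "AO": 80.0, "AC": 380.0, "MO": 460.0}


@pytest.fixture(scope="session")
def clean_record():
    """Noise-free traditional record: exact ground truth, no modulation."""
    cfg = SynthConfig(duration=30.0, mean_rr=1000.0, rr_sd=0.0, noise_sd=0.0,
                      resp_mod_depth=0.0, fp_latencies=dict(TRUE_LATENCIES),
                      seed=11)
    return generate_record(cfg)


@pytest.fixture(scope="session")
def noisy_record():
    """Traditional record with 5% noise and RR variability."""
    cfg = SynthConfig(duration=30.0, mean_rr=900.0, rr_sd=40.0, noise_sd=0.05,
                      fp_latencies=dict(TRUE_LATENCIES), seed=13)
    return generate_record(cfg)
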