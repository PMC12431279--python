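import logging

import numpy as np
import pytest

import wavehr as wh

# Pipeline warnings about edge-region gaps are expected on every run and
# would drown the test output.
logging.getLogger("wavehr").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def modulated_ecg_run():
    """Full pipeline run on the reference modulated ECG.

    600 s at 250 Hz, HR(t) = 1.0 + 0.1 sin(2*pi*0.1*t) Hz, seed 42.
    Shared across tests because detect_hr dominates the suite runtime.
    """
    cfg = wh.SyntheticConfig(
        duration=600.0, lf_amp=0.1, lf_freq=0.1, hf_amp=0.0, seed=42
    )
    record, truth = wh.make_record(cfg)
    fund, harm, diag = wh.detect_hr(record)
    return {
        "config": cfg,
        "record": record,
        "truth": truth,
        "fund": fund,
        "harm": harm,
        "diag": diag,
    }


@pytest.fixture(scope="session")
def constant_ecg_run():
    """Clean constant-rate ECG (1.0 Hz, 300 s) through the pipeline."""
    cfg = wh.SyntheticConfig(duration=300.0, lf_amp=0.0, hf_amp=0.0, seed=1)
    record, truth = wh.make_record(cfg)
    fund, harm, diag = wh.detect_hr(record)
    return {"record": record, "truth": truth, "fund": fund, "harm": harm, "diag": diag}


def interior_mask(times: np.ndarray, t_lo: float, t_hi: float) -> np.ndarray:
    return (times >= t_lo) & (times <= t_hi)
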