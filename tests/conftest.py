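import numpy as np
import pytest

import gawkit as gk

FS_GAW = 4000


@pytest.fixture(scope="session")
def sine_100hz():
    """250 ms of an exact 100 Hz sine at the GAW rate (period = 40 samples)."""
    t = np.arange(1000) / FS_GAW
    return np.sin(2 * np.pi * 100 * t)


@pytest.fixture(scope="session")
def clean_recording():
    """Noise-free, perfectly periodic synthetic recording."""
    cfg = gk.SynthConfig(f0_hz=125, seed=1)
    rec, gt = gk.simulate_recording(cfg)
    return rec, gt


@pytest.fixture(scope="session")
def typical_recording():
    """Mildly perturbed recording close to a healthy phonation."""
    cfg = gk.SynthConfig(
        f0_hz=180, jitter_rel=0.005, shimmer_rel=0.02, gap_rel=0.05,
        lr_phase_delay_rel=0.02, lr_amp_ratio=0.95,
        acoustic_snr_db=30, gaw_noise_rel=0.005, seed=7,
    )
    return gk.simulate_recording(cfg)


@pytest.fixture(scope="session")
def small_cohort_params():
    """Parameter table of a small mixed cohort (both genders), reused by
    screening and norm-table tests."""
    cohort = gk.simulate_cohort((14, 7, 10, 5), seed=42)
    return gk.cohort_parameters(rec for rec, _ in cohort)
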