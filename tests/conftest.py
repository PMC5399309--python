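import numpy as np
import pytest

from mmcsb import DetectorConfig, MMSignal, SimConfig


@pytest.fixture()
def clean_config() -> SimConfig:
    """Noise-free, drift-free generator settings (separability regime)."""
    return SimConfig(noise_sd_mm=0.0, drift_amp_mm=0.0)


@pytest.fixture()
def detector() -> DetectorConfig:
    return DetectorConfig()


def make_sinusoid(
    duration_s: float = 60.0,
    freq_hz: float = 0.25,
    peak_to_trough_mm: float = 0.2,
    fs: float = 10.0,
    baseline_mm: float = -1.0,
    quantize: bool = True,
) -> MMSignal:
    """A breathing-like trace: dips from baseline toward opening and back."""
    t = np.arange(int(round(duration_s * fs))) / fs
    x = baseline_mm - peak_to_trough_mm / 2.0 * (1.0 - np.cos(2 * np.pi * freq_hz * t))
    if quantize:
        x = np.round(x / 0.1) * 0.1
    return MMSignal(samples=x, sampling_rate=fs)
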