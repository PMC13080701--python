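import numpy as np
import pytest

import hepkit as hk


@pytest.fixture(scope="session")
def clean_recording() -> hk.Recording:
    """Noise-free recording: 5 µV heartbeat-locked component on C4+F8,
    60 bpm with no R-R jitter, no artifacts."""
    cfg = hk.SynthRecordingConfig(
        duration_s=120.0,
        noise_sd_uv=0.0,
        hep_amplitude_uv=5.0,
        mean_hr_bpm=60.0,
        hr_sd_bpm=0.0,
        rr_jitter_ms=0.0,
        artifact_rate_per_min=0.0,
        seed=1,
    )
    return hk.generate_recording(cfg)


@pytest.fixture(scope="session")
def clean_peaks(clean_recording) -> hk.RPeakSeries:
    return hk.detect_r_peaks(clean_recording.ecg, clean_recording.sampling_rate_hz)


@pytest.fixture(scope="session")
def noisy_recording() -> hk.Recording:
    """Realistic background: 10 µV noise, mild R-R jitter, no artifacts."""
    cfg = hk.SynthRecordingConfig(
        duration_s=400.0,
        noise_sd_uv=10.0,
        hep_amplitude_uv=5.0,
        mean_hr_bpm=60.0,
        hr_sd_bpm=2.0,
        rr_jitter_ms=20.0,
        artifact_rate_per_min=0.0,
        seed=2,
    )
    return hk.generate_recording(cfg)


def flat_recording(duration_s: float, fs: float = 256.0, subject_id: str = "flat",
                   annotations=()) -> hk.Recording:
    """All-zero recording scaffold for segmentation/epoching tests."""
    n = int(duration_s * fs)
    labels = list(hk.MINIMUM_EEG_CHANNELS) + ["ECG"]
    return hk.Recording(
        subject_id=subject_id,
        channel_labels=labels,
        sampling_rate_hz=fs,
        signal=np.zeros((len(labels), n)),
        ecg_label="ECG",
        annotations=list(annotations),
    )


@pytest.fixture
def make_flat_recording():
    return flat_recording
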