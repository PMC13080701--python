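"""Epoch extraction, rejection gates, back-averaging and compound HEP."""

import numpy as np
import pytest

import hepkit as hk
from hepkit.ecg import RPeakSeries
from hepkit.hep import (
    EpochSet,
    HEPWindows,
    average_and_baseline,
    compute_hep,
    extract_epochs,
    reject_by_amplitude,
)

W = HEPWindows()
FS = 256.0


def _epoch_set(data, peak_times=None, **counts):
    data = np.asarray(data, dtype=np.float64)
    n = data.shape[0]
    defaults = dict(n_total=n, n_rejected_rr=0, n_dropped_boundary=0, n_rejected_ptp=0)
    defaults.update(counts)
    return EpochSet(
        data=data,
        channel_labels=list(hk.MINIMUM_EEG_CHANNELS),
        peak_times_s=np.arange(n, dtype=float) if peak_times is None else peak_times,
        fs=FS,
        windows=W,
        **defaults,
    )


def test_window_sample_conventions():
    assert W.n_samples(FS) == 307  # 1.2 s at 256 Hz
    m = W.measure_index(FS)
    o0, _ = W.epoch_offsets(FS)
    assert (m.start + o0, m.stop - 1 + o0) == (116, 152)  # inclusive endpoints
    b = W.baseline_index(FS)
    assert (b.start + o0, b.stop + o0) == (-90, -26)


def test_epoch_count_arithmetic(clean_recording, clean_peaks):
    """~1 epoch per second at 60 bpm, 307 samples each."""
    epochs = extract_epochs(clean_recording, clean_peaks, W)
    assert epochs.data.shape[1:] == (10, 307)
    assert abs(epochs.n_epochs - 118) <= 2  # 120 beats minus the two edge beats


def test_peak_too_close_to_segment_start_is_dropped(clean_recording, clean_peaks):
    first_peak = clean_peaks.peak_times_s[0]
    epochs = extract_epochs(clean_recording, clean_peaks, W, t0=first_peak - 0.2)
    assert epochs.n_dropped_boundary >= 1
    assert np.all(epochs.peak_times_s - 0.4 >= first_peak - 0.2)


def test_all_short_rr_yields_zero_epochs():
    cfg = hk.SynthRecordingConfig(
        duration_s=60.0, mean_hr_bpm=100.0, hr_sd_bpm=0.0, rr_jitter_ms=0.0,
        noise_sd_uv=0.0, artifact_rate_per_min=0.0, seed=0,
    )
    rec = hk.generate_recording(cfg)  # all R-R = 600 ms < 700 ms
    peaks = hk.detect_r_peaks(rec.ecg, rec.sampling_rate_hz)
    epochs = extract_epochs(rec, peaks, W)
    assert epochs.n_epochs == 0
    assert epochs.n_rejected_rr == epochs.n_total


def test_amplitude_rejection_any_channel_strict():
    n_samp = W.n_samples(FS)
    data = np.zeros((3, 10, n_samp))
    f8 = list(hk.MINIMUM_EEG_CHANNELS).index("F8")
    data[0, f8, 150] = 150.0  # 150 µV spike on F8 only -> rejected
    data[1, f8, 150] = 50.0
    data[1, f8, 160] = -50.0  # exactly 100 µV peak-to-peak -> kept (strict)
    epochs = _epoch_set(data)
    out = reject_by_amplitude(epochs)
    assert out.n_epochs == 2
    assert out.n_rejected_ptp == 1
    # idempotent
    again = reject_by_amplitude(out)
    assert again.n_epochs == 2 and again.n_rejected_ptp == 1


def test_rejection_no_change_when_all_below_threshold():
    data = np.random.default_rng(0).normal(0, 5, size=(20, 10, W.n_samples(FS)))
    out = reject_by_amplitude(_epoch_set(data))
    assert out.n_epochs == 20 and out.n_rejected_ptp == 0


def test_compound_is_sum_of_c4_and_f8(clean_recording, clean_peaks):
    res = compute_hep(clean_recording, clean_peaks, W)
    assert res.compound_amplitude_uv == pytest.approx(
        res.channel_amplitudes_uv["C4"] + res.channel_amplitudes_uv["F8"], abs=1e-9
    )
    assert res.compound_amplitude_uv == pytest.approx(10.0, abs=0.1)
    assert res.valid


def test_constant_offset_cancelled_by_baseline_correction(clean_recording, clean_peaks):
    shifted = clean_recording.copy()
    c4 = shifted.channel_labels.index("C4")
    shifted.signal[c4] += 7.0
    a = compute_hep(clean_recording, clean_peaks, W)
    b = compute_hep(shifted, clean_peaks, W)
    assert b.compound_amplitude_uv == pytest.approx(a.compound_amplitude_uv, abs=1e-3)


def test_min_epoch_validity_gate():
    n_samp = W.n_samples(FS)
    res59 = average_and_baseline(_epoch_set(np.zeros((59, 10, n_samp))))
    res60 = average_and_baseline(_epoch_set(np.zeros((60, 10, n_samp))))
    assert not res59.valid
    assert res60.valid


def test_hep_linearity_over_equal_epoch_grids():
    rng = np.random.default_rng(1)
    x = rng.normal(0, 5, size=(30, 10, W.n_samples(FS)))
    y = rng.normal(0, 5, size=(30, 10, W.n_samples(FS)))
    rx = average_and_baseline(_epoch_set(x))
    ry = average_and_baseline(_epoch_set(y))
    rxy = average_and_baseline(_epoch_set(x + y))
    assert rxy.compound_amplitude_uv == pytest.approx(
        rx.compound_amplitude_uv + ry.compound_amplitude_uv, abs=1e-9
    )


def test_epoch_order_permutation_leaves_results_unchanged():
    rng = np.random.default_rng(2)
    data = rng.normal(0, 5, size=(40, 10, W.n_samples(FS)))
    perm = rng.permutation(40)
    a = average_and_baseline(_epoch_set(data))
    b = average_and_baseline(_epoch_set(data[perm]))
    assert np.allclose(a.channel_waveforms, b.channel_waveforms, atol=1e-10)
    assert a.compound_amplitude_uv == pytest.approx(b.compound_amplitude_uv, abs=1e-10)


def test_sum_of_lead_amplitudes_equals_amplitude_of_summed_waveform():
    rng = np.random.default_rng(3)
    data = rng.normal(0, 5, size=(25, 10, W.n_samples(FS)))
    res = average_and_baseline(_epoch_set(data))
    labels = list(hk.MINIMUM_EEG_CHANNELS)
    summed = res.channel_waveforms[labels.index("C4")] + res.channel_waveforms[labels.index("F8")]
    amp = summed[W.measure_index(FS)].mean()
    assert amp == pytest.approx(res.compound_amplitude_uv, abs=1e-9)


def test_average_matches_naive_two_loop_oracle():
    rng = np.random.default_rng(4)
    for _ in range(20):
        n_ep = rng.integers(2, 8)
        data = rng.normal(0, 10, size=(n_ep, 10, W.n_samples(FS)))
        res = average_and_baseline(_epoch_set(data))
        bl = W.baseline_index(FS)
        me = W.measure_index(FS)
        for ci, label in enumerate(hk.MINIMUM_EEG_CHANNELS):
            wave = np.array([np.mean([data[e, ci, s] for e in range(n_ep)]) for s in range(data.shape[2])])
            wave -= np.mean(wave[bl])
            assert res.channel_amplitudes_uv[label] == pytest.approx(np.mean(wave[me]), abs=1e-9)


def test_missing_compound_lead_flags_result():
    n_samp = W.n_samples(FS)
    es = _epoch_set(np.zeros((70, 10, n_samp)))
    es.channel_labels = [c for c in es.channel_labels if c != "C4"] + ["X1"]
    res = average_and_baseline(es)
    assert np.isnan(res.compound_amplitude_uv)
    assert not res.valid


def test_rejection_accounting_identity(noisy_recording):
    peaks = hk.detect_r_peaks(noisy_recording.ecg, noisy_recording.sampling_rate_hz)
    epochs = reject_by_amplitude(extract_epochs(noisy_recording, peaks, W))
    res = average_and_baseline(epochs)
    assert res.n_used == res.n_epochs_total - res.n_rejected_rr - res.n_rejected_ptp
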