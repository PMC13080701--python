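"""Heartbeat-evoked-potential core: R-locked epoching, rejection, averaging.

The HEP is the EEG potential obtained by back-averaging many segments
time-locked to ECG R waves.  Analysis windows (in seconds relative to the
R wave):

* epoch span:       [-0.400, +0.800)
* baseline:         [-0.350, -0.100)   (mean subtracted per channel)
* measurement:      [+0.455, +0.595]   (window mean = HEP amplitude)

Epoch gates, applied in a fixed order so the counts are well defined:
R-R gate first (interval to next beat < 700 ms removed, strict), then
segment-boundary fit, then the 100 µV peak-to-peak rejection (strict
"exceeds", evaluated on every analysis channel).  A segment average built
from fewer than 60 usable epochs is flagged invalid.

The "compound HEP" is the sum of the window-mean amplitudes at C4 and F8.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .ecg import RPeakSeries, rr_keep_mask
from .io_recordings import MINIMUM_EEG_CHANNELS, Recording

__all__ = [
    "HEPWindows",
    "EpochSet",
    "HEPResult",
    "COMPOUND_CHANNELS",
    "extract_epochs",
    "reject_by_amplitude",
    "average_and_baseline",
    "compute_hep",
]

#: Leads summed into the compound HEP.
COMPOUND_CHANNELS = ("C4", "F8")


@dataclass(frozen=True)
class HEPWindows:
    """Timing and rejection parameters for HEP derivation (seconds / µV)."""

    epoch_start_s: float = -0.400
    epoch_end_s: float = 0.800
    baseline_start_s: float = -0.350
    baseline_end_s: float = -0.100
    measure_start_s: float = 0.455
    measure_end_s: float = 0.595
    reject_ptp_uv: float = 100.0
    min_rr_ms: float = 700.0
    min_epochs: int = 60
    #: interpret reject_ptp_uv as per-channel peak-to-peak (True) or max |V| (False)
    ptp_mode: bool = True

    def __post_init__(self) -> None:
        if not (
            self.epoch_start_s
            < self.baseline_start_s
            < self.baseline_end_s
            < 0
            < self.measure_start_s
            < self.measure_end_s
            <= self.epoch_end_s
        ):
            raise ValueError("window ordering violated")

    # Sample conventions: half-open [round(t*fs), round(t*fs)) offsets
    # relative to the R-peak sample; the measurement window includes both
    # endpoint samples after rounding.

    def epoch_offsets(self, fs: float) -> tuple[int, int]:
        return int(np.rint(self.epoch_start_s * fs)), int(np.rint(self.epoch_end_s * fs))

    def n_samples(self, fs: float) -> int:
        o0, o1 = self.epoch_offsets(fs)
        return o1 - o0

    def baseline_index(self, fs: float) -> slice:
        o0, _ = self.epoch_offsets(fs)
        b0 = int(np.rint(self.baseline_start_s * fs))
        b1 = int(np.rint(self.baseline_end_s * fs))
        return slice(b0 - o0, b1 - o0)

    def measure_index(self, fs: float) -> slice:
        o0, _ = self.epoch_offsets(fs)
        m0 = int(np.rint(self.measure_start_s * fs))
        m1 = int(np.rint(self.measure_end_s * fs))
        return slice(m0 - o0, m1 - o0 + 1)

    def time_axis(self, fs: float) -> np.ndarray:
        o0, o1 = self.epoch_offsets(fs)
        return np.arange(o0, o1) / fs


@dataclass
class EpochSet:
    """R-locked epochs on the analysis channels, with rejection accounting.

    ``n_total`` counts the candidate beats whose epoch fits the segment
    (beats dropped for boundary underflow/overflow are in
    ``n_dropped_boundary`` and are not part of ``n_total``), so that
    n_used = n_total - n_rejected_rr - n_rejected_ptp always holds.
    """

    data: np.ndarray  # (n_epochs, n_channels, n_samples) µV
    channel_labels: list[str]
    peak_times_s: np.ndarray
    fs: float
    windows: HEPWindows
    n_total: int
    n_rejected_rr: int
    n_dropped_boundary: int
    n_rejected_ptp: int = 0

    @property
    def n_epochs(self) -> int:
        return int(self.data.shape[0])

    @property
    def n_used(self) -> int:
        return self.n_total - self.n_rejected_rr - self.n_rejected_ptp

    def subset(self, idx: np.ndarray) -> "EpochSet":
        idx = np.asarray(idx)
        return replace(self, data=self.data[idx], peak_times_s=self.peak_times_s[idx])


@dataclass
class HEPResult:
    """Averaged, baseline-corrected waveforms and window-mean amplitudes."""

    channel_labels: list[str]
    channel_waveforms: np.ndarray  # (n_channels, n_samples) µV, baseline-corrected
    channel_amplitudes_uv: dict[str, float]
    compound_amplitude_uv: float
    n_epochs_total: int
    n_rejected_rr: int
    n_rejected_ptp: int
    n_dropped_boundary: int
    n_used: int
    valid: bool
    fs: float = np.nan
    windows: HEPWindows = field(default_factory=HEPWindows)


def extract_epochs(
    rec: Recording,
    peaks: RPeakSeries,
    w: HEPWindows = HEPWindows(),
    *,
    t0: float | None = None,
    t1: float | None = None,
    channels: list[str] | None = None,
) -> EpochSet:
    """Cut one epoch per kept R peak inside the segment [t0, t1).

    The R-R gate (:func:`hepkit.ecg.rr_keep_mask`, computed on the full peak
    series so the interval to the next beat is known even across the segment
    edge) is applied first; epochs whose window would cross the segment
    bounds are then dropped and counted separately.
    """
    fs = rec.sampling_rate_hz
    t0 = 0.0 if t0 is None else float(t0)
    t1 = rec.duration_s if t1 is None else float(t1)
    if channels is None:
        channels = [c for c in rec.channel_labels if c in MINIMUM_EEG_CHANNELS]
    ch_idx = [rec.channel_labels.index(c) for c in channels]
    o0, o1 = w.epoch_offsets(fs)

    in_seg = (peaks.peak_times_s >= t0) & (peaks.peak_times_s < t1)
    keep_rr_all = rr_keep_mask(peaks, min_rr_ms=w.min_rr_ms, signal_end_s=t1, epoch_after_s=w.epoch_end_s)

    seg_idx = np.nonzero(in_seg)[0]
    kept: list[int] = []
    n_rej_rr = 0
    n_boundary = 0
    r_samples = np.rint(peaks.peak_times_s * fs).astype(int)
    lo_bound = int(np.ceil(t0 * fs))
    hi_bound = int(np.floor(t1 * fs))
    for i in seg_idx:
        if not keep_rr_all[i]:  # R-R gate attributed first
            n_rej_rr += 1
            continue
        s0, s1 = r_samples[i] + o0, r_samples[i] + o1
        if not (s0 >= lo_bound and s1 <= min(hi_bound, rec.n_samples)):
            n_boundary += 1
            continue
        kept.append(i)

    n_total = len(seg_idx) - n_boundary
    n_samp = o1 - o0
    if kept:
        kept_arr = np.asarray(kept)
        gather = (r_samples[kept_arr] + o0)[:, None] + np.arange(n_samp)
        data = rec.signal[np.asarray(ch_idx)][:, gather].transpose(1, 0, 2)
    else:
        data = np.empty((0, len(ch_idx), n_samp))
    return EpochSet(
        data=data,
        channel_labels=list(channels),
        peak_times_s=peaks.peak_times_s[kept],
        fs=fs,
        windows=w,
        n_total=n_total,
        n_rejected_rr=n_rej_rr,
        n_dropped_boundary=n_boundary,
    )


def reject_by_amplitude(epochs: EpochSet, w: HEPWindows | None = None) -> EpochSet:
    """Drop epochs whose amplitude on ANY analysis channel exceeds the gate.

    With ``ptp_mode`` (default) the criterion is per-channel peak-to-peak
    range over the full epoch; the gate is strict, so exactly 100 µV is
    kept.  Counts are updated; the call is idempotent.
    """
    w = w or epochs.windows
    if epochs.n_epochs == 0:
        return epochs
    if w.ptp_mode:
        metric = epochs.data.max(axis=2) - epochs.data.min(axis=2)
    else:
        metric = np.abs(epochs.data).max(axis=2)
    bad = (metric > w.reject_ptp_uv).any(axis=1)
    out = epochs.subset(np.nonzero(~bad)[0])
    out.n_rejected_ptp = epochs.n_rejected_ptp + int(bad.sum())
    return out


def average_and_baseline(epochs: EpochSet, w: HEPWindows | None = None) -> HEPResult:
    """Back-average kept epochs, baseline-correct, measure window means.

    Per channel: waveform = sample-wise mean over epochs, minus its own
    mean over the pre-R baseline window; amplitude = mean of the corrected
    waveform over the measurement window.  Compound = C4 + F8.  The result
    is flagged invalid when fewer than ``min_epochs`` epochs were used.
    """
    w = w or epochs.windows
    fs = epochs.fs
    n_samp = w.n_samples(fs)
    if epochs.n_epochs > 0:
        wave = epochs.data.mean(axis=0)
        wave = wave - wave[:, w.baseline_index(fs)].mean(axis=1, keepdims=True)
        amps = {c: float(wave[i, w.measure_index(fs)].mean()) for i, c in enumerate(epochs.channel_labels)}
    else:
        wave = np.full((len(epochs.channel_labels), n_samp), np.nan)
        amps = {c: np.nan for c in epochs.channel_labels}

    if all(c in amps for c in COMPOUND_CHANNELS):
        compound = float(sum(amps[c] for c in COMPOUND_CHANNELS))
        compound_ok = True
    else:
        compound = np.nan
        compound_ok = False

    valid = epochs.n_used >= w.min_epochs and compound_ok
    return HEPResult(
        channel_labels=list(epochs.channel_labels),
        channel_waveforms=wave,
        channel_amplitudes_uv=amps,
        compound_amplitude_uv=compound,
        n_epochs_total=epochs.n_total,
        n_rejected_rr=epochs.n_rejected_rr,
        n_rejected_ptp=epochs.n_rejected_ptp,
        n_dropped_boundary=epochs.n_dropped_boundary,
        n_used=epochs.n_used,
        valid=valid,
        fs=fs,
        windows=w,
    )


def compute_hep(
    rec: Recording,
    peaks: RPeakSeries,
    w: HEPWindows = HEPWindows(),
    *,
    t0: float | None = None,
    t1: float | None = None,
    channels: list[str] | None = None,
) -> HEPResult:
    """Convenience: epoching + amplitude rejection + averaging in one call."""
    epochs = extract_epochs(rec, peaks, w, t0=t0, t1=t1, channels=channels)
    epochs = reject_by_amplitude(epochs, w)
    return average_and_baseline(epochs, w)
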