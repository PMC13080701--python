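"""Synthetic polygraphy with known ground truth.

Every downstream stage is validated against recordings generated here: a
synthetic ECG lead with QRS complexes on a jittered R-R grid, EEG channels
of Gaussian background noise, and on designated leads a deterministic
heartbeat-locked component whose *measurement-window mean* is exactly the
configured amplitude.  Occasional large transients (> 100 µV) emulate the
movement/electrode artifacts the rejection rules must catch, and annotation
streams emulate the two study arms (seizure telemetry with interictal /
preictal / postictal structure; tilt-table sessions with timestamped
symptom reports).

The heartbeat-locked component is a raised-cosine bump supported on
[0.40, 0.65] s after the R wave: it vanishes both in the pre-R baseline
window [-0.35, -0.1] s and in the QRS cardiac-field region, and is scaled
so its mean over the measurement samples [0.455, 0.595] s equals the target
amplitude analytically.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .hep import HEPWindows
from .io_recordings import (
    MINIMUM_EEG_CHANNELS,
    Annotation,
    Recording,
    write_edf,
)

__all__ = [
    "SynthRecordingConfig",
    "Modulation",
    "SynthCohortConfig",
    "CohortCell",
    "CohortManifest",
    "generate_recording",
    "generate_cohort",
    "build_cohort_recordings",
    "hep_component_template",
    "SEIZURE_TIMELINE",
    "TILT_TIMELINE",
]

#: Support of the heartbeat-locked bump, seconds after the R wave.
HEP_BUMP_SUPPORT_S = (0.40, 0.65)


@dataclass(frozen=True)
class Modulation:
    """A labeled interval during which the generator shifts its parameters.

    ``hep_delta_uv`` adds to the per-lead heartbeat-locked amplitude for
    beats whose R wave falls in [t0, t1); ``hr_delta_bpm`` adds to the
    instantaneous heart rate over the same interval.
    """

    t0_s: float
    t1_s: float
    hep_delta_uv: float = 0.0
    hr_delta_bpm: float = 0.0


@dataclass(frozen=True)
class SynthRecordingConfig:
    duration_s: float = 600.0
    sampling_rate_hz: float = 256.0
    channel_labels: tuple[str, ...] = MINIMUM_EEG_CHANNELS
    ecg_label: str = "ECG"
    mean_hr_bpm: float = 60.0
    hr_sd_bpm: float = 2.0
    rr_jitter_ms: float = 25.0
    hep_amplitude_uv: float = 2.0  # per-lead window mean
    hep_channels: tuple[str, ...] = ("C4", "F8")
    noise_sd_uv: float = 10.0
    artifact_rate_per_min: float = 2.0
    artifact_amplitude_uv: float = 300.0
    qrs_amplitude_uv: float = 800.0
    include_t_wave: bool = False
    cardiac_bleed_uv: float = 0.0  # optional R-locked cardiac-field term on all EEG leads
    modulations: tuple[Modulation, ...] = ()
    annotations: tuple[Annotation, ...] = ()
    seed: int = 0

    def validate(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.sampling_rate_hz <= 0:
            raise ValueError("invalid sampling rate")
        if not (30.0 < self.mean_hr_bpm < 180.0):
            raise ValueError("mean_hr_bpm must be in (30, 180)")
        if not set(self.hep_channels) <= set(self.channel_labels):
            missing = set(self.hep_channels) - set(self.channel_labels)
            raise ValueError(f"hep_channels not a subset of channel_labels: {sorted(missing)}")
        if self.artifact_rate_per_min > 0 and self.artifact_amplitude_uv <= 100.0:
            raise ValueError("artifact_amplitude_uv must exceed 100 µV when artifacts are enabled")
        for m in self.modulations:
            if not np.isfinite(m.hep_delta_uv):
                raise ValueError("modulation shift must be finite")


def hep_component_template(fs: float, windows: HEPWindows = HEPWindows()) -> tuple[np.ndarray, int]:
    """Unit heartbeat-locked bump sampled on the epoch grid.

    Returns ``(template, offset)`` where ``template[k]`` is the component
    value at sample ``offset + k`` relative to the R-peak sample, scaled so
    the mean over the measurement-window samples is exactly 1.  Multiplying
    by the target amplitude therefore injects a component whose analytic
    measurement-window mean equals that amplitude (the baseline window sees
    zero, so baseline correction does not change it).
    """
    t0, t1 = HEP_BUMP_SUPPORT_S
    k0 = int(np.ceil(t0 * fs))
    k1 = int(np.floor(t1 * fs))
    k = np.arange(k0, k1 + 1)
    u = 0.5 * (1.0 - np.cos(2.0 * np.pi * (k / fs - t0) / (t1 - t0)))
    # Mean over the measurement samples (inclusive endpoints, same rounding
    # convention as hep.HEPWindows.measure_index).
    m0 = int(np.rint(windows.measure_start_s * fs))
    m1 = int(np.rint(windows.measure_end_s * fs))
    m = np.arange(m0, m1 + 1)
    vals = np.where((m >= k0) & (m <= k1), u[np.clip(m - k0, 0, u.size - 1)], 0.0)
    mean_measure = vals.mean()
    return u / mean_measure, k0


def _r_peak_samples(cfg: SynthRecordingConfig, rng: np.random.Generator) -> np.ndarray:
    """Beat times quantized to the sample grid, Gaussian-jittered R-R model."""
    fs = cfg.sampling_rate_hz
    phases = rng.uniform(0, 2 * np.pi, size=2)
    times = []
    t = 0.5
    while t < cfg.duration_s:
        hr = cfg.mean_hr_bpm + cfg.hr_sd_bpm * (
            0.7 * np.sin(2 * np.pi * 0.095 * t + phases[0])
            + 0.7 * np.sin(2 * np.pi * 0.275 * t + phases[1])
        )
        for m in cfg.modulations:
            if m.t0_s <= t < m.t1_s:
                hr += m.hr_delta_bpm
        hr = np.clip(hr, 30.0, 180.0)
        times.append(t)
        rr_ms = 60000.0 / hr + rng.normal(0.0, cfg.rr_jitter_ms)
        t += max(rr_ms, 300.0) / 1000.0
    samples = np.rint(np.asarray(times) * fs).astype(int)
    return samples[samples < int(cfg.duration_s * fs)]


def generate_recording(cfg: SynthRecordingConfig, subject_id: str = "synth") -> Recording:
    """Build one synthetic polygraphy :class:`Recording`.

    Ground truth lands in ``rec.meta``: R-peak times (``r_times_s``),
    artifact intervals, and the per-beat injected per-lead amplitude
    (``beat_hep_uv``).  Identical config + seed gives bit-identical output.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    fs = cfg.sampling_rate_hz
    n = int(round(cfg.duration_s * fs))
    labels = list(cfg.channel_labels) + [cfg.ecg_label]
    n_eeg = len(cfg.channel_labels)

    r_samples = _r_peak_samples(cfg, rng)
    r_times = r_samples / fs

    signal = np.zeros((n_eeg + 1, n), dtype=np.float32)
    eeg = signal[:n_eeg]
    ecg = signal[n_eeg]

    # --- ECG lead: Gaussian R deflections (tall, narrow), optional T wave.
    width = max(2, int(round(0.012 * fs)))
    kq = np.arange(-3 * width, 3 * width + 1)
    qrs = cfg.qrs_amplitude_uv * np.exp(-0.5 * (kq / width) ** 2)
    for s in r_samples:
        lo, hi = s + kq[0], s + kq[-1] + 1
        a, b = max(lo, 0), min(hi, n)
        ecg[a:b] += qrs[a - lo : b - lo]
    if cfg.include_t_wave:
        tw = int(round(0.03 * fs))
        kt = np.arange(-3 * tw, 3 * tw + 1)
        t_wave = 0.2 * cfg.qrs_amplitude_uv * np.exp(-0.5 * (kt / tw) ** 2)
        for s in r_samples:
            c = s + int(round(0.30 * fs))
            lo, hi = c + kt[0], c + kt[-1] + 1
            a, b = max(lo, 0), min(hi, n)
            ecg[a:b] += t_wave[a - lo : b - lo]

    # --- EEG channels: white Gaussian background noise.
    if cfg.noise_sd_uv > 0:
        for i in range(n_eeg):
            eeg[i] = rng.normal(0.0, cfg.noise_sd_uv, size=n).astype(np.float32)

    # --- Heartbeat-locked component on designated leads.
    template, offset = hep_component_template(fs)
    beat_amp = np.full(r_samples.size, cfg.hep_amplitude_uv)
    for m in cfg.modulations:
        in_mod = (r_times >= m.t0_s) & (r_times < m.t1_s)
        beat_amp[in_mod] += m.hep_delta_uv
    hep_idx = [list(cfg.channel_labels).index(c) for c in cfg.hep_channels]
    comp = np.zeros(n)
    for s, amp in zip(r_samples, beat_amp):
        lo, hi = s + offset, s + offset + template.size
        a, b = max(lo, 0), min(hi, n)
        if a < b:
            comp[a:b] += amp * template[a - lo : b - lo]
    for i in hep_idx:
        eeg[i] += comp
    if cfg.cardiac_bleed_uv:
        bleed = np.zeros(n)
        for s in r_samples:
            lo, hi = s + kq[0], s + kq[-1] + 1
            a, b = max(lo, 0), min(hi, n)
            bleed[a:b] += (cfg.cardiac_bleed_uv / cfg.qrs_amplitude_uv) * qrs[a - lo : b - lo]
        eeg += bleed[None, :]

    # --- Artifacts: Poisson process of boxcar/spike transients > 100 µV.
    artifact_intervals: list[tuple[float, float]] = []
    if cfg.artifact_rate_per_min > 0:
        n_art = rng.poisson(cfg.artifact_rate_per_min * cfg.duration_s / 60.0)
        for _ in range(n_art):
            t_start = rng.uniform(0.0, cfg.duration_s)
            dur = rng.uniform(0.2, 0.5)
            a = int(round(t_start * fs))
            b = min(n, a + int(round(dur * fs)))
            if b <= a:
                continue
            chans = rng.choice(n_eeg, size=rng.integers(1, min(3, n_eeg) + 1), replace=False)
            shape = rng.choice(["boxcar", "spike"])
            sign = rng.choice([-1.0, 1.0])
            if shape == "boxcar":
                eeg[chans[:, None], np.arange(a, b)[None, :]] += sign * cfg.artifact_amplitude_uv
            else:
                tt = np.linspace(0, np.pi, b - a)
                eeg[chans[:, None], np.arange(a, b)[None, :]] += sign * cfg.artifact_amplitude_uv * np.sin(tt)[None, :]
            artifact_intervals.append((a / fs, b / fs))

    anns = sorted(cfg.annotations, key=lambda x: x.onset_s)
    for ann in anns:
        if ann.onset_s + ann.duration_s > cfg.duration_s + 1e-9:
            raise ValueError("annotation interval outside the recording")
    return Recording(
        subject_id=subject_id,
        channel_labels=labels,
        sampling_rate_hz=fs,
        signal=signal,
        ecg_label=cfg.ecg_label,
        annotations=list(anns),
        meta={
            "r_times_s": r_times,
            "artifact_intervals_s": artifact_intervals,
            "beat_hep_uv": beat_amp,
            "config_seed": cfg.seed,
        },
    )


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

#: Seizure-arm subject timeline (seconds): interictal mark, then one event
#: with a full 5-min preictal window and a 5-min postictal tail.
SEIZURE_TIMELINE = {
    "duration_s": 950.0,
    "interictal": (5.0, 310.0),
    "onset_s": 620.0,
    "event_duration_s": 20.0,
}

#: Tilt-table-arm timeline: a psychological report early (never HEP-shifted)
#: and a bodily (cardiac) report late, whose 2-min pre-report window carries
#: the condition's HEP shift.
TILT_TIMELINE = {
    "duration_s": 600.0,
    "psych_report_s": 250.0,
    "bodily_report_s": 520.0,
}


@dataclass(frozen=True)
class CohortCell:
    group: str  # FS | ES | functional_syncope | VVS
    semiology: str = "none"  # motile | non_motile | none
    shift_uv: float = 0.0  # compound-HEP shift injected in the modulated window
    hr_change_bpm: float = 0.0

    @property
    def name(self) -> str:
        return f"{self.group}_{self.semiology}" if self.semiology != "none" else self.group


@dataclass(frozen=True)
class SynthCohortConfig:
    n_subjects_per_cell: int = 15
    cells: tuple[CohortCell, ...] = (
        CohortCell("FS", "motile", shift_uv=-3.0, hr_change_bpm=-3.0),
        CohortCell("FS", "non_motile", shift_uv=3.0, hr_change_bpm=3.0),
        CohortCell("ES", "motile", shift_uv=0.0),
        CohortCell("ES", "non_motile", shift_uv=0.0),
    )
    interictal_hep_uv: float = 4.0  # compound (C4 + F8) baseline amplitude
    between_subject_sd_uv: float = 1.0  # SD of the per-subject compound shift
    recording: SynthRecordingConfig = field(default_factory=SynthRecordingConfig)
    include_postictal: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects_per_cell < 2:
            raise ValueError("n_subjects_per_cell must be >= 2")
        for c in self.cells:
            if not np.isfinite(c.shift_uv):
                raise ValueError("cell shift must be finite")


@dataclass
class CohortManifest:
    subjects: pd.DataFrame  # subject_id, group, semiology, path
    ground_truth: pd.DataFrame
    out_dir: Path | None = None


def _subject_recording(
    cell: CohortCell,
    subject_id: str,
    base_cfg: SynthRecordingConfig,
    interictal_compound_uv: float,
    shift_compound_uv: float,
    seed: int,
    include_postictal: bool = True,
) -> Recording:
    """One subject's Recording for either study arm, with annotations."""
    n_leads = len(base_cfg.hep_channels)
    per_lead_base = interictal_compound_uv / n_leads
    per_lead_shift = shift_compound_uv / n_leads

    if cell.group in ("FS", "ES"):
        tl = SEIZURE_TIMELINE
        onset, ev_dur = tl["onset_s"], tl["event_duration_s"]
        anns = (
            Annotation(tl["interictal"][0], tl["interictal"][1] - tl["interictal"][0], "interictal_mark"),
            Annotation(onset, 0.0, "seizure_onset", event_type=cell.group, semiology=cell.semiology, event_id="ev1"),
            Annotation(onset + ev_dur, 0.0, "seizure_offset", event_type=cell.group, semiology=cell.semiology, event_id="ev1"),
        )
        mods = (
            Modulation(onset - 300.0, onset, hep_delta_uv=per_lead_shift, hr_delta_bpm=cell.hr_change_bpm),
        )
        # The postictal tail can be omitted when only the interictal-to-
        # preictal change is under study (keeps large simulation sweeps fast).
        duration = tl["duration_s"] if include_postictal else onset + ev_dur + 10.0
    else:  # tilt-table arm
        tl = TILT_TIMELINE
        anns = (
            Annotation(tl["psych_report_s"], 0.0, "symptom_report", symptom_category="psychological"),
            Annotation(tl["bodily_report_s"], 0.0, "symptom_report", symptom_category="cardiac"),
        )
        mods = (
            Modulation(tl["bodily_report_s"] - 120.0, tl["bodily_report_s"], hep_delta_uv=per_lead_shift, hr_delta_bpm=cell.hr_change_bpm),
        )
        duration = tl["duration_s"]

    cfg = replace(
        base_cfg,
        duration_s=duration,
        hep_amplitude_uv=per_lead_base,
        modulations=mods,
        annotations=anns,
        seed=seed,
    )
    return generate_recording(cfg, subject_id=subject_id)


def build_cohort_recordings(config: SynthCohortConfig) -> tuple[list[Recording], pd.DataFrame]:
    """In-memory cohort: one Recording per subject plus the ground-truth table.

    The ground-truth compound amplitudes are the analytic measurement-window
    means of the injected components (exact before noise, by construction of
    the template).
    """
    config.validate()
    master = np.random.default_rng(config.seed)
    recs: list[Recording] = []
    rows = []
    for ci, cell in enumerate(config.cells):
        for k in range(config.n_subjects_per_cell):
            subject_id = f"sub-{cell.name}-{k:03d}"
            # Stable per-subject child seeds: adding subjects/cells later
            # does not perturb earlier subjects.
            child = np.random.SeedSequence([config.seed, ci, k]).generate_state(1)[0] % (2**31 - 1)
            b_rng = np.random.default_rng(child)
            interictal = config.interictal_hep_uv + b_rng.normal(0.0, config.between_subject_sd_uv)
            shift = cell.shift_uv + b_rng.normal(0.0, config.between_subject_sd_uv)
            rec = _subject_recording(
                cell, subject_id, config.recording, interictal, shift, int(child),
                include_postictal=config.include_postictal,
            )
            recs.append(rec)
            rows.append(
                {
                    "subject_id": subject_id,
                    "group": cell.group,
                    "semiology": cell.semiology,
                    "true_interictal_compound_uv": interictal,
                    "true_modulated_compound_uv": interictal + shift,
                    "true_shift_compound_uv": shift,
                    "true_hr_change_bpm": cell.hr_change_bpm,
                    "seed": int(child),
                }
            )
    return recs, pd.DataFrame(rows)


def generate_cohort(config: SynthCohortConfig, out_dir: str | Path) -> CohortManifest:
    """Write one EDF+ per subject plus ground-truth and manifest CSVs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    recs, truth = build_cohort_recordings(config)
    rows = []
    for rec in recs:
        path = out_dir / f"{rec.subject_id}.edf"
        write_edf(rec, path)
        group = truth.loc[truth.subject_id == rec.subject_id, "group"].iloc[0]
        semio = truth.loc[truth.subject_id == rec.subject_id, "semiology"].iloc[0]
        rows.append({"subject_id": rec.subject_id, "group": group, "semiology": semio, "path": str(path)})
    subjects = pd.DataFrame(rows)
    subjects.to_csv(out_dir / "manifest.csv", index=False)
    truth.to_csv(out_dir / "ground_truth.csv", index=False)
    return CohortManifest(subjects=subjects, ground_truth=truth, out_dir=out_dir)
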