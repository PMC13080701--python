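"""Turning annotations into analysis segments and subject-level summaries.

Arm 1 (seizure telemetry): interictal / preictal / postictal windows around
annotated events.  Events shorter than 5 s are excluded; the preictal window
is the up-to-5-min interval ending at onset (truncated at the recording
start and at any earlier event's offset), the postictal window the
up-to-5-min interval starting at offset; the interictal segment is the
longest annotated artifact-free wakeful interval of at least 5 min.

Arm 2 (tilt table): for each symptom report, the 2-min pre-report window of
its category; the category baseline is everything more than 2 min before
every report of that category.  Because tilt-table heart rates leave fewer
usable beats, each subject x condition HEP is a 20x bootstrap over epochs.

Subject summaries hold one row per subject x event type x semiology, so a
subject contributes at most one value per statistical comparison
(pseudoreplication guard).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .hep import COMPOUND_CHANNELS, EpochSet, HEPWindows
from .io_recordings import Recording

__all__ = [
    "SegmentSpec",
    "select_event_segments",
    "select_symptom_windows",
    "bootstrap_subject_hep",
    "summarize_subjects",
    "MIN_EVENT_DURATION_S",
    "PERI_EVENT_WINDOW_S",
    "MIN_INTERICTAL_S",
    "PRE_SYMPTOM_WINDOW_S",
]

MIN_EVENT_DURATION_S = 5.0
PERI_EVENT_WINDOW_S = 300.0
MIN_INTERICTAL_S = 300.0
PRE_SYMPTOM_WINDOW_S = 120.0

ROLES = ("interictal", "preictal", "postictal", "pre_symptom", "baseline")


@dataclass(frozen=True)
class SegmentSpec:
    """A labeled half-open analysis interval [t0, t1) tied to one subject."""

    subject_id: str
    t0_s: float
    t1_s: float
    role: str
    event_type: str = "none"
    semiology: str = "none"
    symptom_category: str = "none"
    event_id: str = ""

    def __post_init__(self) -> None:
        if self.t1_s <= self.t0_s:
            raise ValueError(f"empty segment [{self.t0_s}, {self.t1_s})")
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}")
        dur = self.t1_s - self.t0_s
        if self.role in ("preictal", "postictal") and dur > PERI_EVENT_WINDOW_S + 1e-9:
            raise ValueError("peri-event segment exceeds 5 min")
        if self.role == "interictal" and dur < MIN_INTERICTAL_S - 1e-9:
            raise ValueError("interictal segment shorter than 5 min")
        # a merged pre-symptom window (overlapping reports of one category)
        # may span more than 2 min; each constituent report contributes at
        # most 2 min, so no point lies > 2 min before every covered report

    @property
    def duration_s(self) -> float:
        return self.t1_s - self.t0_s


def select_event_segments(rec: Recording) -> list[SegmentSpec]:
    """Interictal/preictal/postictal segments from seizure annotations.

    Events are onset/offset annotation pairs (matched by event id, else by
    order); events shorter than 5 s emit nothing.  Preictal windows are
    truncated at the previous event's offset, postictal windows at the next
    event's onset and the recording end.
    """
    onsets = [a for a in rec.annotations if a.kind == "seizure_onset"]
    offsets = [a for a in rec.annotations if a.kind == "seizure_offset"]
    marks = [a for a in rec.annotations if a.kind == "interictal_mark"]
    if not (onsets or marks):
        raise ValueError("no seizure or interictal annotations present")

    by_id = {a.event_id: a for a in offsets}
    events = []
    for i, on in enumerate(sorted(onsets, key=lambda a: a.onset_s)):
        off = by_id.get(on.event_id)
        if off is None and i < len(offsets):
            off = sorted(offsets, key=lambda a: a.onset_s)[i]
        if off is None or off.onset_s <= on.onset_s:
            continue
        # mixed/unclassifiable semiology events are excluded
        if on.event_type == "none" or on.semiology == "none":
            continue
        events.append((on, off))
    events.sort(key=lambda pair: pair[0].onset_s)

    segments: list[SegmentSpec] = []

    # Interictal: longest marked interval >= 5 min, tie-broken by earliest onset.
    eligible = [m for m in marks if m.duration_s >= MIN_INTERICTAL_S]
    if eligible:
        best = max(eligible, key=lambda m: (m.duration_s, -m.onset_s))
        segments.append(
            SegmentSpec(rec.subject_id, best.onset_s, best.onset_s + best.duration_s, "interictal")
        )

    for i, (on, off) in enumerate(events):
        if off.onset_s - on.onset_s < MIN_EVENT_DURATION_S:
            continue
        pre0 = max(0.0, on.onset_s - PERI_EVENT_WINDOW_S)
        if i > 0:
            pre0 = max(pre0, events[i - 1][1].onset_s)
        post1 = min(rec.duration_s, off.onset_s + PERI_EVENT_WINDOW_S)
        if i + 1 < len(events):
            post1 = min(post1, events[i + 1][0].onset_s)
        meta = dict(event_type=on.event_type, semiology=on.semiology, event_id=on.event_id or f"ev{i}")
        if on.onset_s > pre0:
            segments.append(SegmentSpec(rec.subject_id, pre0, on.onset_s, "preictal", **meta))
        if post1 > off.onset_s:
            segments.append(SegmentSpec(rec.subject_id, off.onset_s, post1, "postictal", **meta))
    return segments


def _merge_intervals(intervals: list[tuple[float, float]]) -> list[tuple[float, float]]:
    merged: list[list[float]] = []
    for a, b in sorted(intervals):
        if merged and a <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    return [(a, b) for a, b in merged]


def select_symptom_windows(rec: Recording) -> list[SegmentSpec]:
    """Pre-symptom (2 min before each report) and per-category baselines.

    Overlapping pre-report windows of the same category are merged.  The
    baseline for a category covers every point more than 2 min earlier than
    all of that category's reports; exclusion is per category (a report of
    one category does not shrink another category's baseline).
    """
    reports = [a for a in rec.annotations if a.kind == "symptom_report"]
    segments: list[SegmentSpec] = []
    if not reports:
        if rec.duration_s > 0:
            segments.append(SegmentSpec(rec.subject_id, 0.0, rec.duration_s, "baseline"))
        return segments

    by_cat: dict[str, list[float]] = {}
    for r in reports:
        by_cat.setdefault(r.symptom_category, []).append(r.onset_s)

    for cat, times in sorted(by_cat.items()):
        pres = _merge_intervals([(max(0.0, t - PRE_SYMPTOM_WINDOW_S), t) for t in times])
        for a, b in pres:
            if b > a:
                segments.append(
                    SegmentSpec(rec.subject_id, a, b, "pre_symptom", symptom_category=cat)
                )
        base_end = min(times) - PRE_SYMPTOM_WINDOW_S
        if base_end > 0:
            segments.append(SegmentSpec(rec.subject_id, 0.0, base_end, "baseline", symptom_category=cat))
    return segments


def bootstrap_subject_hep(epochs: EpochSet, n_boot: int = 20, seed: int = 0) -> float:
    """Mean compound HEP over ``n_boot`` with-replacement epoch resamples.

    Epochs are first put in canonical (R-peak time) order so the value does
    not depend on how the epoch set was assembled.  Each resample is
    averaged, baseline-corrected and measured exactly like a plain average;
    the subject's value is the mean of the resample amplitudes.
    """
    if epochs.n_epochs == 0:
        raise ValueError("bootstrap requires at least one usable epoch")
    w, fs = epochs.windows, epochs.fs
    order = np.argsort(epochs.peak_times_s)
    data = epochs.data[order]
    ch = [epochs.channel_labels.index(c) for c in COMPOUND_CHANNELS]
    rng = np.random.default_rng(seed)
    n = data.shape[0]
    vals = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        wave = data[idx].mean(axis=0)
        wave = wave - wave[:, w.baseline_index(fs)].mean(axis=1, keepdims=True)
        vals[b] = wave[np.ix_(ch, range(*w.measure_index(fs).indices(wave.shape[1])))].mean(axis=1).sum()
    return float(vals.mean())


def summarize_subjects(scores: pd.DataFrame) -> pd.DataFrame:
    """Collapse per-segment scores to one row per subject x type x semiology.

    ``scores`` has one row per scored segment with columns: subject_id,
    role, event_type, semiology, event_id, compound_uv, valid, mean_hr_bpm,
    rmssd_ms, lf_power, hf_power.  An event contributes a change value only
    when both its preictal average and the subject's interictal average are
    valid (the <60-epoch gate); invalid events are omitted from the means.
    """
    rows = []
    for subject, sub in scores.groupby("subject_id"):
        inter = sub[(sub.role == "interictal") & sub.valid]
        inter_hep = float(inter.compound_uv.mean()) if len(inter) else np.nan
        inter_hr = float(inter.mean_hr_bpm.mean()) if len(inter) else np.nan
        inter_rmssd = float(inter.rmssd_ms.mean()) if len(inter) else np.nan
        events = sub[sub.role.isin(["preictal", "postictal"])]
        for (etype, semio), cell in events.groupby(["event_type", "semiology"]):
            changes, pres, posts, hr_changes, pre_rmssds = [], [], [], [], []
            for _, ev in cell[cell.role == "preictal"].iterrows():
                if ev.valid:
                    pres.append(ev.compound_uv)
                    pre_rmssds.append(ev.rmssd_ms)
                    if np.isfinite(inter_hep):
                        changes.append(ev.compound_uv - inter_hep)
                        hr_changes.append(ev.mean_hr_bpm - inter_hr)
            for _, ev in cell[cell.role == "postictal"].iterrows():
                if ev.valid:
                    posts.append(ev.compound_uv)
            rows.append(
                {
                    "subject_id": subject,
                    "event_type": etype,
                    "semiology": semio,
                    "hep_interictal_uv": inter_hep,
                    "hep_preictal_uv": float(np.mean(pres)) if pres else np.nan,
                    "hep_postictal_uv": float(np.mean(posts)) if posts else np.nan,
                    "hep_change_uv": float(np.mean(changes)) if changes else np.nan,
                    "hr_change_bpm": float(np.mean(hr_changes)) if hr_changes else np.nan,
                    "rmssd_interictal_ms": inter_rmssd,
                    "rmssd_preictal_ms": float(np.mean(pre_rmssds)) if pre_rmssds else np.nan,
                    "n_events": int((cell.role == "preictal").sum()),
                    "has_interictal": bool(len(inter)),
                }
            )
    return pd.DataFrame(rows)
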