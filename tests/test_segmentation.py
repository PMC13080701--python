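"""Peri-event and symptom-window segmentation, the 20x subject bootstrap,
and subject-level summarization."""

import numpy as np
import pandas as pd
import pytest

import hepkit as hk
from hepkit.hep import HEPWindows, extract_epochs
from hepkit.segmentation import (
    bootstrap_subject_hep,
    select_event_segments,
    select_symptom_windows,
    summarize_subjects,
)

A = hk.Annotation


def _seizure_rec(make_flat_recording, events, duration=900.0, interictal=(0.0, 350.0)):
    anns = [A(interictal[0], interictal[1] - interictal[0], "interictal_mark")]
    for i, (on, off) in enumerate(events):
        anns.append(A(on, 0.0, "seizure_onset", event_type="FS", semiology="motile", event_id=f"e{i}"))
        anns.append(A(off, 0.0, "seizure_offset", event_type="FS", semiology="motile", event_id=f"e{i}"))
    return make_flat_recording(duration, annotations=anns)


def test_peri_event_window_arithmetic(make_flat_recording):
    rec = _seizure_rec(make_flat_recording, [(400.0, 430.0)])
    segs = {s.role: s for s in select_event_segments(rec)}
    assert (segs["preictal"].t0_s, segs["preictal"].t1_s) == (100.0, 400.0)
    assert (segs["postictal"].t0_s, segs["postictal"].t1_s) == (430.0, 730.0)
    assert (segs["interictal"].t0_s, segs["interictal"].t1_s) == (0.0, 350.0)


def test_events_shorter_than_5s_excluded(make_flat_recording):
    rec = _seizure_rec(make_flat_recording, [(400.0, 404.0)])
    roles = {s.role for s in select_event_segments(rec)}
    assert "preictal" not in roles and "postictal" not in roles


def test_preictal_truncated_at_recording_start(make_flat_recording):
    rec = _seizure_rec(make_flat_recording, [(120.0, 140.0)], interictal=(400.0, 750.0))
    segs = {s.role: s for s in select_event_segments(rec)}
    assert (segs["preictal"].t0_s, segs["preictal"].t1_s) == (0.0, 120.0)


def test_preictal_truncated_at_previous_event_offset(make_flat_recording):
    rec = _seizure_rec(make_flat_recording, [(300.0, 320.0), (500.0, 520.0)])
    pres = [s for s in select_event_segments(rec) if s.role == "preictal"]
    second = [s for s in pres if s.event_id == "e1"][0]
    assert second.t0_s == 320.0  # previous offset, not 200 s


def test_interictal_longest_eligible_mark_earliest_tiebreak(make_flat_recording):
    anns = [
        A(0.0, 310.0, "interictal_mark"),
        A(320.0, 400.0, "interictal_mark"),   # longest
        A(750.0, 100.0, "interictal_mark"),   # too short
    ]
    rec = make_flat_recording(900.0, annotations=anns)
    seg = [s for s in select_event_segments(rec) if s.role == "interictal"][0]
    assert (seg.t0_s, seg.t1_s) == (320.0, 720.0)


def test_no_annotations_raises(make_flat_recording):
    with pytest.raises(ValueError):
        select_event_segments(make_flat_recording(100.0))


def test_symptom_window_single_report(make_flat_recording):
    rec = make_flat_recording(900.0, annotations=[A(500.0, 0.0, "symptom_report", symptom_category="cardiac")])
    segs = select_symptom_windows(rec)
    pre = [s for s in segs if s.role == "pre_symptom"][0]
    base = [s for s in segs if s.role == "baseline"][0]
    assert (pre.t0_s, pre.t1_s) == (380.0, 500.0)
    assert base.t1_s <= 380.0


def test_symptom_windows_merge_same_category(make_flat_recording):
    anns = [
        A(300.0, 0.0, "symptom_report", symptom_category="cardiac"),
        A(350.0, 0.0, "symptom_report", symptom_category="cardiac"),
    ]
    rec = make_flat_recording(900.0, annotations=anns)
    pres = [s for s in select_symptom_windows(rec) if s.role == "pre_symptom"]
    assert len(pres) == 1
    assert (pres[0].t0_s, pres[0].t1_s) == (180.0, 350.0)


def test_symptom_baseline_per_category_exclusion(make_flat_recording):
    anns = [
        A(200.0, 0.0, "symptom_report", symptom_category="psychological"),
        A(500.0, 0.0, "symptom_report", symptom_category="cardiac"),
    ]
    rec = make_flat_recording(900.0, annotations=anns)
    bases = {s.symptom_category: s for s in select_symptom_windows(rec) if s.role == "baseline"}
    assert bases["cardiac"].t1_s == 380.0  # psych report does not shrink cardiac baseline
    assert bases["psychological"].t1_s == 80.0


def test_no_reports_whole_record_is_baseline(make_flat_recording):
    rec = make_flat_recording(600.0)
    segs = select_symptom_windows(rec)
    assert [s.role for s in segs] == ["baseline"]
    assert (segs[0].t0_s, segs[0].t1_s) == (0.0, 600.0)


# ---------------------------------------------------------------------------
# within-subject bootstrap
# ---------------------------------------------------------------------------

def _epochs(clean_recording, clean_peaks, t1=None):
    return extract_epochs(clean_recording, clean_peaks, HEPWindows(), t1=t1)


def test_bootstrap_of_identical_epochs_equals_plain_average(clean_recording, clean_peaks):
    epochs = _epochs(clean_recording, clean_peaks)
    # noise-free generator: every epoch is identical, so any resample
    # reproduces the plain compound HEP exactly
    plain = hk.average_and_baseline(epochs).compound_amplitude_uv
    boot = bootstrap_subject_hep(epochs, n_boot=20, seed=1)
    assert boot == pytest.approx(plain, abs=1e-6)


def test_bootstrap_seeded_determinism_and_order_invariance(noisy_recording):
    peaks = hk.detect_r_peaks(noisy_recording.ecg, noisy_recording.sampling_rate_hz)
    epochs = extract_epochs(noisy_recording, peaks, HEPWindows())
    a = bootstrap_subject_hep(epochs, seed=7)
    b = bootstrap_subject_hep(epochs, seed=7)
    assert a == b
    perm = np.random.default_rng(0).permutation(epochs.n_epochs)
    shuffled = epochs.subset(perm)
    c = bootstrap_subject_hep(shuffled, seed=7)
    assert c == pytest.approx(a, abs=1e-9)


def test_bootstrap_converges_to_plain_average(noisy_recording):
    peaks = hk.detect_r_peaks(noisy_recording.ecg, noisy_recording.sampling_rate_hz)
    epochs = extract_epochs(noisy_recording, peaks, HEPWindows())
    plain = hk.average_and_baseline(epochs).compound_amplitude_uv
    few = abs(bootstrap_subject_hep(epochs, n_boot=5, seed=3) - plain)
    many = abs(bootstrap_subject_hep(epochs, n_boot=2000, seed=3) - plain)
    assert many < 0.2  # law of large numbers: resample mean ~ plain mean
    assert many < few + 0.05


def test_bootstrap_requires_epochs(clean_recording, clean_peaks):
    empty = extract_epochs(clean_recording, clean_peaks, HEPWindows(), t0=0.0, t1=0.5)
    with pytest.raises(ValueError):
        bootstrap_subject_hep(empty)


# ---------------------------------------------------------------------------
# subject summaries
# ---------------------------------------------------------------------------

def _score_row(subject, role, value, valid=True, etype="FS", semio="motile", event="e0", hr=60.0):
    return {
        "subject_id": subject, "role": role, "event_type": etype if role != "interictal" else "none",
        "semiology": semio if role != "interictal" else "none", "event_id": event,
        "compound_uv": value, "valid": valid, "mean_hr_bpm": hr,
        "rmssd_ms": 30.0, "lf_power": 1.0, "hf_power": 1.0,
    }


def test_summary_averages_events_within_subject():
    rows = [_score_row("s1", "interictal", 1.0, event="")]
    for i, pre in enumerate([-1.0, -2.0, -3.0]):
        rows.append(_score_row("s1", "preictal", 1.0 + pre, event=f"e{i}"))
    out = summarize_subjects(pd.DataFrame(rows))
    assert len(out) == 1
    assert out.hep_change_uv.iloc[0] == pytest.approx(-2.0)


def test_summary_one_row_per_type_semiology():
    rows = [
        _score_row("s1", "interictal", 0.0, event=""),
        _score_row("s1", "preictal", 1.0, etype="FS", semio="motile"),
        _score_row("s1", "preictal", 2.0, etype="FS", semio="non_motile", event="e1"),
    ]
    out = summarize_subjects(pd.DataFrame(rows))
    assert len(out) == 2
    assert set(zip(out.event_type, out.semiology)) == {("FS", "motile"), ("FS", "non_motile")}


def test_invalid_event_omitted_from_subject_mean():
    rows = [
        _score_row("s1", "interictal", 0.0, event=""),
        _score_row("s1", "preictal", -2.0),
        _score_row("s1", "preictal", -100.0, valid=False, event="e1"),  # <60 epochs
    ]
    out = summarize_subjects(pd.DataFrame(rows))
    assert out.hep_change_uv.iloc[0] == pytest.approx(-2.0)


def test_subject_without_interictal_has_no_change_value():
    rows = [_score_row("s1", "preictal", -2.0)]
    out = summarize_subjects(pd.DataFrame(rows))
    assert np.isnan(out.hep_change_uv.iloc[0])
    assert not out.has_interictal.iloc[0]
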