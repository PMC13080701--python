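"""End-to-end orchestration of the two study arms.

``run_pipeline`` drives: EDF loading -> band-pass + ASR -> R-peak detection
-> segmentation (seizure or tilt-table arm) -> HEP derivation with the
rejection gates -> subject summaries -> the inference battery, writing CSV
tables, a JSON results file and a JSON-lines audit log.  The in-memory
entry point ``run_pipeline_recordings`` runs the identical analysis on
:class:`Recording` objects, which is what the simulation harnesses use.

Seeding: a master seed is expanded into per-subject and per-test child
seeds keyed on stable identifiers (hashes of subject ids / test names), so
adding a subject or test never perturbs the others' draws.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import segmentation as seg
from . import stats as st
from .ecg import compute_hrv, detect_r_peaks
from .hep import EpochSet, HEPWindows, average_and_baseline, extract_epochs, reject_by_amplitude
from .io_recordings import Recording, read_edf
from .preprocess import CleanReport, PreprocessConfig, preprocess

__all__ = ["RunConfig", "RunReport", "run_pipeline", "run_pipeline_recordings", "child_seed"]

#: the four planned seizure-arm contrasts -> Bonferroni alpha 0.05/4
SEIZURE_FAMILY = 4
#: six symptom categories -> Bonferroni alpha 0.05/6
SYMPTOM_FAMILY = 6


def child_seed(master: int, *keys: str) -> int:
    """Deterministic child seed from the master seed and stable string keys."""
    h = hashlib.blake2b("|".join(keys).encode(), digest_size=4).hexdigest()
    ss = np.random.SeedSequence([int(master), int(h, 16)])
    return int(ss.generate_state(1)[0] % (2**31 - 1))


@dataclass
class RunConfig:
    input_manifest: str | Path | None = None
    arm: str = "seizure"  # or "tilt_table"
    windows: HEPWindows = field(default_factory=HEPWindows)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    n_resamples: int = 2000
    n_boot_subject: int = 20
    base_alpha: float = 0.05
    outlier_z: float = 3.0
    run_ancova: bool = True
    seed: int = 0
    out_dir: str | Path | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        windows = HEPWindows(**raw.pop("windows", {}))
        pre = PreprocessConfig(**raw.pop("preprocess", {}))
        return cls(windows=windows, preprocess=pre, **raw)


@dataclass
class RunReport:
    arm: str
    segments: pd.DataFrame
    hep_table: pd.DataFrame
    summaries: pd.DataFrame
    tests: list[st.TestResult]
    audit: list[dict]
    ancova: list[st.TestResult] = field(default_factory=list)
    excluded_outliers: dict = field(default_factory=dict)

    def tests_frame(self) -> pd.DataFrame:
        return pd.DataFrame([t.to_dict() for t in self.tests + self.ancova])


# ---------------------------------------------------------------------------
# Per-subject scoring
# ---------------------------------------------------------------------------

def _concat_epochs(parts: list[EpochSet]) -> EpochSet | None:
    parts = [p for p in parts if p is not None]
    if not parts:
        return None
    base = parts[0]
    data = np.concatenate([p.data for p in parts], axis=0)
    times = np.concatenate([p.peak_times_s for p in parts])
    return EpochSet(
        data=data,
        channel_labels=base.channel_labels,
        peak_times_s=times,
        fs=base.fs,
        windows=base.windows,
        n_total=sum(p.n_total for p in parts),
        n_rejected_rr=sum(p.n_rejected_rr for p in parts),
        n_dropped_boundary=sum(p.n_dropped_boundary for p in parts),
        n_rejected_ptp=sum(p.n_rejected_ptp for p in parts),
    )


def _score_segment(rec: Recording, peaks, spec: seg.SegmentSpec, w: HEPWindows) -> tuple[dict, dict, EpochSet]:
    epochs = extract_epochs(rec, peaks, w, t0=spec.t0_s, t1=spec.t1_s)
    epochs = reject_by_amplitude(epochs, w)
    result = average_and_baseline(epochs, w)
    hrv = compute_hrv(peaks.restrict(spec.t0_s, spec.t1_s))
    row = {
        "subject_id": spec.subject_id,
        "role": spec.role,
        "event_type": spec.event_type,
        "semiology": spec.semiology,
        "symptom_category": spec.symptom_category,
        "event_id": spec.event_id,
        "t0_s": spec.t0_s,
        "t1_s": spec.t1_s,
        "compound_uv": result.compound_amplitude_uv,
        "valid": result.valid,
        "n_used": result.n_used,
        "mean_hr_bpm": hrv.mean_hr_bpm,
        "rmssd_ms": hrv.rmssd_ms,
        "lf_power": hrv.lf_power,
        "hf_power": hrv.hf_power,
    }
    for c, a in result.channel_amplitudes_uv.items():
        row[f"amp_{c}_uv"] = a
    audit = {
        "subject_id": spec.subject_id,
        "role": spec.role,
        "event_id": spec.event_id,
        "n_candidates": result.n_epochs_total + result.n_dropped_boundary,
        "n_total": result.n_epochs_total,
        "n_rejected_rr": result.n_rejected_rr,
        "n_rejected_ptp": result.n_rejected_ptp,
        "n_dropped_boundary": result.n_dropped_boundary,
        "n_used": result.n_used,
        "valid": result.valid,
    }
    return row, audit, epochs


def _prepare_subject(rec: Recording, cfg: RunConfig) -> tuple[Recording, object, CleanReport]:
    marks = [a for a in rec.annotations if a.kind == "interictal_mark"]
    cal = (marks[0].onset_s, marks[0].onset_s + marks[0].duration_s) if marks else None
    clean, report = preprocess(rec, cfg.preprocess, calibration_interval_s=cal)
    peaks = detect_r_peaks(rec.ecg, rec.sampling_rate_hz)
    return clean, peaks, report


# ---------------------------------------------------------------------------
# Arm 1: seizure telemetry
# ---------------------------------------------------------------------------

def _analyze_seizure_arm(
    recs: list[Recording], groups: pd.DataFrame, cfg: RunConfig
) -> RunReport:
    score_rows, audit, seg_rows = [], [], []
    for rec in recs:
        clean, peaks, report = _prepare_subject(rec, cfg)
        audit.append({"subject_id": rec.subject_id, "stage": "asr", **report.to_dict()})
        try:
            segments = seg.select_event_segments(clean)
        except ValueError as exc:
            audit.append({"subject_id": rec.subject_id, "stage": "segmentation", "error": str(exc)})
            continue
        for spec in segments:
            seg_rows.append(spec.__dict__)
            row, a, _ = _score_segment(clean, peaks, spec, cfg.windows)
            score_rows.append(row)
            audit.append({"stage": "hep", **a})

    scores = pd.DataFrame(score_rows)
    summaries = seg.summarize_subjects(scores) if len(scores) else pd.DataFrame()

    tests: list[st.TestResult] = []
    ancova: list[st.TestResult] = []
    excluded: dict[str, list] = {}
    if len(summaries):
        cells = [("FS", "motile"), ("FS", "non_motile"), ("ES", "motile"), ("ES", "non_motile")]
        clean_vals: dict[tuple[str, str], np.ndarray] = {}
        for etype, semio in cells:
            cell = summaries[(summaries.event_type == etype) & (summaries.semiology == semio)]
            vals = cell.hep_change_uv.dropna().to_numpy()
            if vals.size >= 3:
                vals, excl = st.exclude_outliers(vals, ids=cell.dropna(subset=["hep_change_uv"]).subject_id.tolist(), z_max=cfg.outlier_z)
                if excl:
                    excluded[f"{etype}_{semio}"] = excl
            clean_vals[(etype, semio)] = vals
            if vals.size >= 2:
                tests.append(
                    st.bootstrap_test(
                        vals,
                        kind="one_sample",
                        n_resamples=cfg.n_resamples,
                        seed=child_seed(cfg.seed, "one_sample", etype, semio),
                        name=f"hep_change_vs_zero[{etype}_{semio}]",
                    )
                )
        contrasts = [
            (("FS", "motile"), ("ES", "motile")),
            (("FS", "non_motile"), ("ES", "non_motile")),
            (("FS", "motile"), ("FS", "non_motile")),
            (("ES", "motile"), ("ES", "non_motile")),
        ]
        for ca, cb in contrasts:
            a, b = clean_vals.get(ca, np.empty(0)), clean_vals.get(cb, np.empty(0))
            if a.size >= 2 and b.size >= 2:
                v = np.concatenate([a, b])
                g = np.array([0] * a.size + [1] * b.size)
                tests.append(
                    st.bootstrap_test(
                        v,
                        kind="two_sample",
                        group=g,
                        n_resamples=cfg.n_resamples,
                        seed=child_seed(cfg.seed, "two_sample", *ca, *cb),
                        name=f"hep_change[{'_'.join(ca)}]_vs_[{'_'.join(cb)}]",
                    )
                )
        tests = st.bonferroni_gate(tests, SEIZURE_FAMILY, cfg.base_alpha)

        if cfg.run_ancova:
            for etype in ("FS", "ES"):
                sub = summaries[summaries.event_type == etype].dropna(subset=["hep_change_uv", "hr_change_bpm"])
                if sub.semiology.nunique() >= 2 and len(sub) > 4:
                    spec = st.ModelSpec(
                        outcome="hep_change_uv",
                        fixed_factors=("semiology",),
                        covariates=("hr_change_bpm",),
                        strata=("semiology",),
                    )
                    ancova.append(
                        st.bootstrap_test(
                            kind="ols_F",
                            summaries=sub,
                            model=spec,
                            term="semiology",
                            n_resamples=cfg.n_resamples,
                            seed=child_seed(cfg.seed, "ancova", etype),
                            name=f"ancova_semiology[{etype}]",
                        )
                    )

    return RunReport(
        arm="seizure",
        segments=pd.DataFrame(seg_rows),
        hep_table=scores,
        summaries=summaries,
        tests=tests,
        ancova=ancova,
        audit=audit,
        excluded_outliers=excluded,
    )


# ---------------------------------------------------------------------------
# Arm 2: tilt table
# ---------------------------------------------------------------------------

def _analyze_tilt_arm(recs: list[Recording], groups: pd.DataFrame, cfg: RunConfig) -> RunReport:
    rows, audit, seg_rows = [], [], []
    group_of = dict(zip(groups.subject_id, groups.group)) if len(groups) else {}
    for rec in recs:
        clean, peaks, report = _prepare_subject(rec, cfg)
        audit.append({"subject_id": rec.subject_id, "stage": "asr", **report.to_dict()})
        segments = seg.select_symptom_windows(clean)
        by_cat: dict[str, dict[str, list[EpochSet]]] = {}
        for spec in segments:
            seg_rows.append(spec.__dict__)
            row, a, epochs = _score_segment(clean, peaks, spec, cfg.windows)
            audit.append({"stage": "hep", **a})
            by_cat.setdefault(spec.symptom_category, {}).setdefault(spec.role, []).append(epochs)
        for cat, roles in by_cat.items():
            if cat == "none" or "pre_symptom" not in roles or "baseline" not in roles:
                continue
            pre = _concat_epochs(roles["pre_symptom"])
            base = _concat_epochs(roles["baseline"])
            if pre is None or base is None or pre.n_epochs == 0 or base.n_epochs == 0:
                continue
            pre_val = seg.bootstrap_subject_hep(
                pre, n_boot=cfg.n_boot_subject, seed=child_seed(cfg.seed, "boot", rec.subject_id, cat, "pre")
            )
            base_val = seg.bootstrap_subject_hep(
                base, n_boot=cfg.n_boot_subject, seed=child_seed(cfg.seed, "boot", rec.subject_id, cat, "base")
            )
            rows.append(
                {
                    "subject_id": rec.subject_id,
                    "group": group_of.get(rec.subject_id, "unknown"),
                    "symptom_category": cat,
                    "hep_pre_symptom_uv": pre_val,
                    "hep_baseline_uv": base_val,
                    "n_pre_epochs": pre.n_epochs,
                    "n_base_epochs": base.n_epochs,
                }
            )

    summaries = pd.DataFrame(rows)
    tests: list[st.TestResult] = []
    if len(summaries):
        alpha = cfg.base_alpha / SYMPTOM_FAMILY
        for (grp, cat), sub in summaries.groupby(["group", "symptom_category"]):
            if len(sub) >= 2:
                tests.append(
                    st.paired_symptom_test(
                        sub.hep_pre_symptom_uv.to_numpy(),
                        sub.hep_baseline_uv.to_numpy(),
                        alpha=alpha,
                        name=f"paired_symptom[{grp}:{cat}]",
                    )
                )
    return RunReport(
        arm="tilt_table",
        segments=pd.DataFrame(seg_rows),
        hep_table=pd.DataFrame(),
        summaries=summaries,
        tests=tests,
        audit=audit,
    )


# ---------------------------------------------------------------------------
# Entry points
# ---------------------------------------------------------------------------

def run_pipeline_recordings(
    recs: list[Recording], cfg: RunConfig, groups: pd.DataFrame | None = None
) -> RunReport:
    """Run the configured arm on in-memory recordings.

    ``groups`` maps subject_id -> group (and semiology) for the tilt arm;
    the seizure arm reads event type/semiology from the annotations.
    """
    if not recs:
        raise ValueError("no recordings to analyze (empty manifest)")
    groups = groups if groups is not None else pd.DataFrame(columns=["subject_id", "group"])
    if cfg.arm == "seizure":
        report = _analyze_seizure_arm(recs, groups, cfg)
    elif cfg.arm == "tilt_table":
        report = _analyze_tilt_arm(recs, groups, cfg)
    else:
        raise ValueError(f"unknown arm {cfg.arm!r}")
    if cfg.out_dir is not None:
        _write_outputs(report, Path(cfg.out_dir))
    return report


def run_pipeline(cfg: RunConfig) -> RunReport:
    """Load the manifest's EDF+ files and run the configured arm."""
    if cfg.input_manifest is None:
        raise ValueError("RunConfig.input_manifest is required")
    manifest = pd.read_csv(cfg.input_manifest)
    if manifest.empty:
        raise ValueError("empty manifest: nothing to analyze")
    recs = [read_edf(r.path, subject_id=r.subject_id) for r in manifest.itertuples()]
    return run_pipeline_recordings(recs, cfg, groups=manifest)


def _write_outputs(report: RunReport, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    report.segments.to_csv(out_dir / "segments.csv", index=False)
    report.hep_table.to_csv(out_dir / "hep_table.csv", index=False)
    report.summaries.to_csv(out_dir / "subject_summaries.csv", index=False)
    report.tests_frame().to_csv(out_dir / "test_results.csv", index=False)
    with open(out_dir / "test_results.json", "w") as fh:
        json.dump([t.to_dict() for t in report.tests + report.ancova], fh, indent=2, default=float)
    with open(out_dir / "audit.jsonl", "w") as fh:
        for entry in report.audit:
            fh.write(json.dumps(entry, default=float) + "\n")
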