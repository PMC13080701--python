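"""EDF+ I/O and the in-memory polygraphy containers.

A :class:`Recording` is the unit every pipeline stage consumes: an ordered
channel-by-sample matrix in microvolts, one designated ECG lead, and a list
of typed :class:`Annotation` events (seizure onset/offset, interictal marks,
tilt-table symptom reports).

Reading goes through :func:`mne.io.read_raw_edf`.  Writing is handled by a
minimal 16-bit EDF+ writer (:func:`write_edf`) with TAL annotation records,
sufficient for round-tripping the synthetic cohorts this package generates.
"""

from __future__ import annotations

import datetime as _dt
import math
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "Annotation",
    "Recording",
    "ValidationReport",
    "MINIMUM_EEG_CHANNELS",
    "ANNOTATION_KINDS",
    "SYMPTOM_CATEGORIES",
    "read_edf",
    "write_edf",
    "validate_montage",
    "normalize_label",
    "parse_annotation_description",
    "format_annotation_description",
]

#: Minimum scalp montage required for inclusion.
MINIMUM_EEG_CHANNELS = ("Fz", "Fp1", "Fp2", "F3", "F4", "F7", "F8", "C3", "Cz", "C4")

ANNOTATION_KINDS = ("seizure_onset", "seizure_offset", "interictal_mark", "symptom_report", "other")
SYMPTOM_CATEGORIES = ("cardiac", "respiratory", "abdominal", "cephalic", "peripheral", "psychological", "none")
EVENT_TYPES = ("FS", "ES", "functional_syncope", "VVS", "none")
SEMIOLOGIES = ("motile", "non_motile", "none")

#: Label aliases for the ECG lead across site dialects.
DEFAULT_ECG_ALIASES = ("ECG", "EKG", "ECG1", "ECG2", "ECG1-ECG2", "EKG1", "EKG2")


@dataclass(frozen=True)
class Annotation:
    """A typed, timestamped event parsed from an EDF+ annotation."""

    onset_s: float
    duration_s: float = 0.0
    kind: str = "other"
    label: str = ""
    symptom_category: str = "none"
    semiology: str = "none"
    event_type: str = "none"
    event_id: str = ""

    def __post_init__(self) -> None:
        if self.onset_s < 0:
            raise ValueError(f"annotation onset must be >= 0, got {self.onset_s}")
        if self.duration_s < 0:
            raise ValueError(f"annotation duration must be >= 0, got {self.duration_s}")
        if self.kind not in ANNOTATION_KINDS:
            raise ValueError(f"unknown annotation kind {self.kind!r}")
        if (self.symptom_category != "none") != (self.kind == "symptom_report"):
            raise ValueError("symptom_category must be set exactly for symptom_report annotations")


@dataclass
class Recording:
    """Multichannel polygraphy in microvolts plus its annotation stream."""

    subject_id: str
    channel_labels: list[str]
    sampling_rate_hz: float
    signal: np.ndarray  # (n_channels, n_samples), microvolts
    ecg_label: str
    annotations: list[Annotation] = field(default_factory=list)
    start_time: _dt.datetime = _dt.datetime(2000, 1, 1, 0, 0, 0, tzinfo=_dt.timezone.utc)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        # float32 signals are kept as-is (the generator uses them to halve
        # memory traffic); anything else is promoted to float64.
        self.signal = np.asarray(self.signal)
        if self.signal.dtype != np.float32:
            self.signal = self.signal.astype(np.float64, copy=False)
        if self.signal.ndim != 2 or self.signal.shape[0] != len(self.channel_labels):
            raise ValueError("signal must be (n_channels, n_samples) matching channel_labels")
        if not np.all(np.isfinite(self.signal)):
            raise ValueError("signal contains non-finite values")
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling rate must be positive")
        if self.ecg_label not in self.channel_labels:
            raise ValueError(f"ECG lead {self.ecg_label!r} not among channel labels")

    @property
    def duration_s(self) -> float:
        return self.signal.shape[1] / self.sampling_rate_hz

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def eeg_labels(self) -> list[str]:
        return [c for c in self.channel_labels if c != self.ecg_label]

    def channel(self, label: str) -> np.ndarray:
        return self.signal[self.channel_labels.index(label)]

    @property
    def ecg(self) -> np.ndarray:
        return self.channel(self.ecg_label)

    def copy(self) -> "Recording":
        return replace(self, signal=self.signal.copy(), annotations=list(self.annotations), meta=dict(self.meta))


@dataclass(frozen=True)
class ValidationReport:
    """Montage check outcome: never raises, only reports."""

    passed: bool
    present: tuple[str, ...]
    missing: tuple[str, ...]
    ignored: tuple[str, ...]

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        status = "pass" if self.passed else "fail"
        parts = [f"montage {status}"]
        if self.missing:
            parts.append("missing: " + ", ".join(self.missing))
        if self.ignored:
            parts.append("ignored: " + ", ".join(self.ignored))
        return "; ".join(parts)


# ---------------------------------------------------------------------------
# Label normalization
# ---------------------------------------------------------------------------

_CANONICAL = {c.lower(): c for c in MINIMUM_EEG_CHANNELS}


def normalize_label(label: str, ecg_aliases: Sequence[str] = DEFAULT_ECG_ALIASES) -> str:
    """Strip recorder prefixes/whitespace and map label dialects.

    ``"EEG Fz-REF"`` -> ``"Fz"``; ``"EKG"`` -> ``"ECG"``.  Unknown labels are
    returned trimmed but otherwise untouched.
    """
    lab = label.strip()
    lab = re.sub(r"^(EEG|POL)\s+", "", lab, flags=re.IGNORECASE)
    lab = re.sub(r"-(REF|LE|AVG)$", "", lab, flags=re.IGNORECASE)
    lab = lab.strip()
    if lab.lower() in _CANONICAL:
        return _CANONICAL[lab.lower()]
    if lab.upper() in {a.upper() for a in ecg_aliases}:
        return "ECG"
    return lab


# ---------------------------------------------------------------------------
# Annotation descriptions
# ---------------------------------------------------------------------------

def format_annotation_description(ann: Annotation) -> str:
    """Serialize an Annotation into the structured ``kind;key=value`` text."""
    parts = [ann.kind]
    if ann.event_type != "none":
        parts.append(f"type={ann.event_type}")
    if ann.semiology != "none":
        parts.append(f"semiology={ann.semiology}")
    if ann.symptom_category != "none":
        parts.append(f"category={ann.symptom_category}")
    if ann.event_id:
        parts.append(f"event={ann.event_id}")
    if ann.label:
        parts.append(f"label={ann.label}")
    return ";".join(parts)


def parse_annotation_description(
    onset_s: float,
    duration_s: float,
    description: str,
    mapping: Mapping[str, Mapping[str, str]] | None = None,
) -> Annotation:
    """Parse one EDF+ annotation into a typed :class:`Annotation`.

    ``mapping`` translates site-specific free text to the structured fields
    (keys are exact description strings after stripping; values are field
    dicts, e.g. ``{"sz start": {"kind": "seizure_onset", "event_type": "ES"}}``).
    Descriptions following the ``kind;key=value`` convention are parsed
    directly; anything else becomes ``kind="other"``.
    """
    desc = description.strip()
    fields: dict[str, str] = {}
    if mapping and desc in mapping:
        fields = dict(mapping[desc])
    else:
        head, *rest = desc.split(";")
        if head in ANNOTATION_KINDS:
            fields["kind"] = head
            for item in rest:
                if "=" in item:
                    k, v = item.split("=", 1)
                    key = {"type": "event_type", "event": "event_id", "category": "symptom_category"}.get(k, k)
                    fields[key] = v
    kind = fields.get("kind", "other")
    return Annotation(
        onset_s=float(onset_s),
        duration_s=float(duration_s),
        kind=kind,
        label=fields.get("label", desc if kind == "other" else ""),
        symptom_category=fields.get("symptom_category", "none"),
        semiology=fields.get("semiology", "none"),
        event_type=fields.get("event_type", "none"),
        event_id=fields.get("event_id", ""),
    )


# ---------------------------------------------------------------------------
# EDF+ writing (16-bit, one annotation channel)
# ---------------------------------------------------------------------------

def _ascii(value: str, width: int) -> bytes:
    b = value.encode("ascii")
    if len(b) > width:
        raise ValueError(f"field {value!r} exceeds {width} ascii bytes")
    return b.ljust(width)


def _num(value: float, width: int) -> bytes:
    for fmt in (f"{{:.{p}g}}" for p in range(10, 0, -1)):
        s = fmt.format(value)
        if len(s) <= width and "e" not in s and "E" not in s:
            return _ascii(s, width)
    raise ValueError(f"cannot format {value} in {width} chars")


def write_edf(
    rec: Recording,
    path: str | Path,
    *,
    digital_max: int = 32767,
    physical_range_uv: float | None = None,
) -> Path:
    """Write a Recording as a 16-bit EDF+C file with TAL annotations.

    Signals are stored with symmetric physical ranges chosen per channel
    (or a fixed ``physical_range_uv``), so the quantization step is
    ``2*phys_max / (2*digital_max)``.  Record duration is 1 s; the trailing
    partial second is zero-padded in the final record.
    """
    path = Path(path)
    fs = rec.sampling_rate_hz
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    fs = int(round(fs))
    n_ch = len(rec.channel_labels)
    n_records = max(1, math.ceil(rec.n_samples / fs))

    # Per-channel physical scaling.
    phys_max = []
    for i in range(n_ch):
        if physical_range_uv is not None:
            pm = float(physical_range_uv)
        else:
            pm = float(np.max(np.abs(rec.signal[i]))) * 1.05
            pm = max(pm, 1.0)
        phys_max.append(float(f"{pm:.5g}"))

    # TAL payloads, one per data record.
    tals: list[bytes] = []
    per_record_anns: list[list[Annotation]] = [[] for _ in range(n_records)]
    for ann in rec.annotations:
        idx = min(int(ann.onset_s), n_records - 1)
        per_record_anns[idx].append(ann)
    for r in range(n_records):
        chunks = [f"+{r}\x14\x14\x00".encode("ascii")]
        for ann in per_record_anns[r]:
            onset = f"+{ann.onset_s:.4f}".rstrip("0").rstrip(".")
            if onset == "+":
                onset = "+0"
            tal = onset
            if ann.duration_s > 0:
                dur = f"{ann.duration_s:.4f}".rstrip("0").rstrip(".")
                tal += "\x15" + dur
            tal += "\x14" + format_annotation_description(ann) + "\x14\x00"
            chunks.append(tal.encode("utf-8"))
        tals.append(b"".join(chunks))
    ann_bytes = max(len(t) for t in tals)
    ann_samples = math.ceil(ann_bytes / 2) + 8  # headroom, int16 samples

    labels = list(rec.channel_labels) + ["EDF Annotations"]
    n_sig = n_ch + 1
    header_bytes = 256 * (1 + n_sig)

    start = rec.start_time
    head = b"".join(
        [
            _ascii("0", 8),
            _ascii(f"X X X {rec.subject_id[:60] or 'X'}", 80),
            _ascii("Startdate 01-JAN-2000 X X X", 80),
            _ascii(start.strftime("%d.%m.%y"), 8),
            _ascii(start.strftime("%H.%M.%S"), 8),
            _ascii(str(header_bytes), 8),
            _ascii("EDF+C", 44),
            _ascii(str(n_records), 8),
            _ascii("1", 8),
            _ascii(str(n_sig), 4),
        ]
    )

    def sig_field(values: Iterable[bytes]) -> bytes:
        return b"".join(values)

    dims = ["uV"] * n_ch + [""]
    pmins = [-pm for pm in phys_max] + [-1.0]
    pmaxs = list(phys_max) + [1.0]
    dmins = [-digital_max] * n_ch + [-32768]
    dmaxs = [digital_max] * n_ch + [32767]
    spr = [fs] * n_ch + [ann_samples]

    head += sig_field(_ascii(lab, 16) for lab in labels)
    head += sig_field(_ascii("", 80) for _ in labels)
    head += sig_field(_ascii(d, 8) for d in dims)
    head += sig_field(_num(v, 8) for v in pmins)
    head += sig_field(_num(v, 8) for v in pmaxs)
    head += sig_field(_num(v, 8) for v in dmins)
    head += sig_field(_num(v, 8) for v in dmaxs)
    head += sig_field(_ascii("", 80) for _ in labels)
    head += sig_field(_ascii(str(s), 8) for s in spr)
    head += sig_field(_ascii("", 32) for _ in labels)
    assert len(head) == header_bytes

    # Digitize once, pad to whole records.
    total = n_records * fs
    padded = np.zeros((n_ch, total))
    padded[:, : rec.n_samples] = rec.signal
    digital = np.empty((n_ch, total), dtype="<i2")
    for i in range(n_ch):
        scale = dmaxs[i] / phys_max[i]
        digital[i] = np.clip(np.rint(padded[i] * scale), -digital_max, digital_max).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(head)
        for r in range(n_records):
            fh.write(digital[:, r * fs : (r + 1) * fs].tobytes())
            tal = tals[r].ljust(ann_samples * 2, b"\x00")
            fh.write(tal)
    return path


# ---------------------------------------------------------------------------
# EDF reading
# ---------------------------------------------------------------------------

def read_edf(
    path: str | Path,
    *,
    subject_id: str | None = None,
    ecg_label: str | None = None,
    required_channels: Sequence[str] = MINIMUM_EEG_CHANNELS,
    annotation_mapping: Mapping[str, Mapping[str, str]] | None = None,
    validate: bool = True,
) -> Recording:
    """Load an EDF/EDF+ file into a :class:`Recording` (signals in µV).

    Channel labels are normalized (case, whitespace, ``"EEG "`` prefixes,
    ECG dialects); annotations are parsed into typed events.  With
    ``validate=True`` a missing required lead or ECG raises ``ValueError``
    naming the missing channel.
    """
    import mne

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    labels = [normalize_label(ch) for ch in raw.ch_names]
    fs = float(raw.info["sfreq"])
    signal = raw.get_data() * 1e6  # mne loads Volts

    if ecg_label is None:
        ecg_candidates = [lab for lab in labels if lab == "ECG"]
        if not ecg_candidates:
            raise ValueError("no ECG channel found (looked for ECG/EKG aliases)")
        ecg_label = ecg_candidates[0]
    elif ecg_label not in labels:
        raise ValueError(f"configured ECG lead {ecg_label!r} not present")

    annotations = [
        parse_annotation_description(on, du, de, annotation_mapping)
        for on, du, de in zip(raw.annotations.onset, raw.annotations.duration, raw.annotations.description)
    ]
    rec = Recording(
        subject_id=subject_id or path.stem,
        channel_labels=labels,
        sampling_rate_hz=fs,
        signal=signal,
        ecg_label=ecg_label,
        annotations=annotations,
    )
    if validate:
        report = validate_montage(rec, required=required_channels)
        if not report.passed:
            raise ValueError(f"missing required channels: {', '.join(report.missing)}")
    return rec


def validate_montage(rec: Recording, required: Sequence[str] = MINIMUM_EEG_CHANNELS) -> ValidationReport:
    """Report present/missing required leads; extra channels are only flagged."""
    present = tuple(c for c in required if c in rec.channel_labels)
    missing = tuple(c for c in required if c not in rec.channel_labels)
    ignored = tuple(c for c in rec.channel_labels if c not in required and c != rec.ecg_label)
    return ValidationReport(passed=not missing, present=present, missing=missing, ignored=ignored)
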