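# Methods

## The measurement

The heartbeat evoked potential (HEP) indexes cortical processing of cardiac
afferent signals.  It is obtained by back-averaging EEG segments time-locked
to ECG R waves: epochs span −0.400 to +0.800 s around each R peak, each
averaged channel is baseline-corrected to its mean over −0.350 to −0.100 s
before the R wave, and the HEP amplitude is the mean of the corrected
average over +0.455 to +0.595 s — a window late enough to avoid the T-wave
cardiac field.  Inference uses the *compound HEP*, the sum of the window
means at C4 and F8, which keeps the multiple-comparison burden at one value
per segment.

Three gates protect the average, applied in a fixed order so the epoch
accounting is reproducible:

1. **R-R gate** — a beat followed by an interval shorter than 700 ms is
   removed (strict `<`), so the next QRS cannot contaminate the post-R
   window.  The final beat of a segment is kept only if ≥ 0.8 s of signal
   remains after it.
2. **Boundary gate** — epochs whose window would cross the segment edges
   are dropped and counted separately.
3. **Amplitude gate** — an epoch is rejected when its peak-to-peak range
   exceeds 100 µV (strict; exactly 100 µV survives) on *any* analysis
   channel.  "Maximum potential difference" is read as per-channel
   peak-to-peak; a flag (`HEPWindows.ptp_mode`) switches to max |V|.

A segment average built from fewer than 60 usable epochs is flagged invalid
and excluded from all subject summaries.

Window-to-sample conversion: half-open ranges `[round(t·fs), round(t·fs))`
relative to the R-peak sample; the measurement window includes both endpoint
samples after rounding.  At 256 Hz an epoch is 307 samples and the
measurement window samples 116…152 inclusive.

## Preprocessing

The acquisition band-pass (0.53–70 Hz) is realized as a 4th-order
Butterworth applied forward-backward (zero phase preserves evoked-response
latency).  Only EEG channels are filtered; the ECG lead is never modified.
Signals are used as-recorded (referential); an optional common-average
re-reference flag exists and defaults to off.

Artifact subspace reconstruction (ASR) runs on the band-passed EEG with a
cutoff of 20: over half-overlapping 0.5 s windows, window-covariance
eigencomponents whose peak projection exceeds 20 × the calibration standard
deviation along that direction are projected out.  Calibration statistics
come from the cleanest contiguous 60 s (lowest worst-block RMS), searched
within the annotated interictal interval when one exists.  Statistics are
taken about zero rather than the window mean — the band-passed signal is
zero-mean, and centering on a window contaminated by a large transient
would bias the level the window is reconstructed around.  Windows with no
flagged component pass through bit-identical, so artifact-free data is
untouched; a cheap screen (worst channel-vector norm against
`cutoff·√λ_min` of the calibration covariance, evaluated in float32 with a
5 % margin) makes the scan linear-time.  Recordings shorter than the
calibration length skip ASR with a warning recorded in the clean report.

## ECG processing

R peaks are detected with a derivative/energy detector (5–30 Hz zero-phase
band-pass, squared derivative, 150 ms moving integration, adaptive
threshold, 250 ms refractory period), refined to the extremum of |filtered
ECG| so polarity is irrelevant.  The contract is accuracy on ground-truth
synthetic ECG (every beat within one sample), not any named algorithm.

HRV metrics: RMSSD (ms) from successive R-R differences; LF (0.04–0.15 Hz)
and HF (0.15–0.40 Hz) band powers (ms²) from a Welch spectrum of the R-R
tachogram cubic-interpolated at 4 Hz.  Spectral metrics require ≥ 2 min of
beats and are flagged otherwise.  The heart-rate-change covariate is
preictal minus interictal mean heart rate, computed on the same segments as
the HEP.

## Segmentation

**Seizure arm.**  Events are onset/offset annotation pairs; events shorter
than 5 s are excluded.  Preictal = up to 300 s ending at onset, truncated at
the recording start and at the previous event's offset; postictal = up to
300 s from offset, truncated symmetrically.  The interictal segment is the
longest annotated artifact-free wakeful interval ≥ 5 min (ties broken by
earliest onset).  Per-event values are averaged within subject × event type
× semiology so each subject contributes one value per comparison
(pseudoreplication guard); an event enters the mean only when both its
preictal average and the subject's interictal average pass the 60-epoch
gate.  Events with unclassifiable type or semiology are dropped.

**Tilt-table arm.**  For each clinician-annotated symptom report, the
pre-symptom window is the 120 s ending at the report; overlapping windows
of one category merge (a merged window may span more than 120 s, but no
point in it lies more than 120 s before every covered report).  The
category baseline is everything more than 120 s before *all* of that
category's reports; the exclusion is per category (a flag-controlled
choice — a psychological report does not shrink the cardiac baseline).
Because tilt-table heart rates leave fewer usable beats, each subject ×
condition HEP is the mean of 20 with-replacement epoch resamples
(epochs in canonical R-time order; seed derived from subject id so the
value is independent of assembly order).

## Inference

All tests operate on subject-level values.  Outliers are removed in a
single pass at |z| > 3 computed from the full sample's mean and SD (ddof 1);
an all-equal sample removes nothing.  Note that with fewer than ~11 values
a single-pass z can never exceed 3, so tiny groups are effectively
ungated — a property of the rule, not a bug.

* **One-/two-sample bootstrapped t-tests**: 2000 with-replacement resamples
  at the subject level, groups as strata.  The null reference distribution
  resamples *re-centered* data (each group shifted to its own mean), and
  the empirical two-tailed p uses the +1-smoothed estimator
  p = (1 + #{|T*| ≥ |T|}) / (B + 1), which is calibrated and never zero.
  Significance is judged on the empirical p.
* **ANCOVA**: OLS with semiology (and event type) as fixed factors and
  heart-rate change as covariate; type-II sums of squares for robustness to
  unbalanced cells.  The "bootstrapped mean F" is the mean F over case
  resamples within strata; the empirical p resamples an outcome with the
  term's fitted effect removed (null-transformed case resampling — the
  resampling scheme was an open design choice).
* **Paired symptom tests**: classical paired t within subjects, judged at
  α = 0.05/6 ≈ 0.0083 (six symptom categories).  A zero-variance nonzero
  difference is degenerate for t; it is flagged and treated as significant.
* **Multiplicity**: the four planned seizure contrasts are judged at
  α = 0.05/4 = 0.0125 via a Bonferroni gate.

Linear mixed models are deliberately out of scope (singular fits on this
design); subject-level averaging plus stratified resampling is the
supported path.

## Synthetic data: what it emulates and what it does not

The generator produces EDF+-writable polygraphy with known ground truth:

* **ECG** — Gaussian R deflections (≈ 800 µV, 12 ms wide) on an R-R grid
  with Gaussian jitter (default 25 ms SD) plus slow sinusoidal heart-rate
  modulation (0.095/0.275 Hz, scaled by `hr_sd_bpm`), truncated at 300 ms.
  A T wave is optional; only R timing matters downstream.
* **EEG** — white Gaussian noise (default 10 µV SD) per channel.
* **HEP component** — a raised-cosine bump supported on 0.40–0.65 s post-R
  on C4 and F8, scaled so its mean over the measurement samples equals the
  configured amplitude *analytically*; it vanishes in the baseline window
  and the QRS region, so ground-truth bookkeeping is exact before noise.
* **Artifacts** — a Poisson process of 0.2–0.5 s boxcar/spike transients
  (> 100 µV, default 300 µV at 2/min) on one to three random channels.
* **Annotations** — interictal marks, seizure onset/offset pairs carrying
  event type/semiology, or timestamped symptom reports by category.

Cohorts place one event per subject with a full 5-min preictal window (the
condition's compound-HEP shift applies uniformly over it, matching the
annotated window) and, in the tilt arm, one early psychological report
(never shifted) and one late bodily report whose 2-min pre-report window
carries the shift.  Per-subject baselines and shifts get independent
Gaussian between-subject variation (default SD 1 µV); per-subject seeds
are derived stably from (cohort seed, cell index, subject index) so adding
cells or subjects never perturbs existing ones.

Not emulated: 1/f EEG spectra, volume-conducted cardiac field (beyond an
optional R-locked bleed term), ectopy, electrode drift, sleep staging, or
semiologically mixed events.  Passing tests therefore demonstrate correct
*machinery* — window arithmetic, gating, averaging, calibration of the
inference — not robustness to every physiological confound of real
telemetry.

One known, deliberate property: with short R-R intervals the previous
beat's component tail can graze the baseline window, biasing absolute HEP
amplitudes slightly downward (≈ 0.1 µV at 60 bpm with 20 ms jitter).  This
mirrors the real cardiac-overlap problem that motivates the 700 ms R-R
gate; change scores are essentially unaffected because the bias is common
to both conditions.

## Effect-size and size choices

No real-data shift magnitude in µV is available, so simulation presets are
free parameters chosen once for ~80–95 % power at realistic n: compound
shifts of ±3 µV (seizure arm, 15 subjects/cell) and ±2 µV (tilt arm, 19
subjects/group) against 1 µV between-subject SD and 10 µV background
noise.  Default interictal compound amplitude is 4 µV.

Problem sizes in the validation harness: recovery checks use 400 s
recordings (~400 beats); bootstrap calibration uses 2000 null simulations
of n = 20 at 2000 resamples; directional recovery uses 50 seeded cohorts
for the seizure arm and 20 for the tilt arm.  `scripts/acceptance.py`
reports the same quantities at reduced replicate counts (500 simulations,
12 and 8 cohorts) so a full reproduction completes quickly on one CPU.
Large simulation sweeps run the identical analysis code on in-memory
recordings, omitting the postictal tail when only the interictal-to-
preictal change is under study; the EDF+ write/read round trip is verified
separately to move compound HEP by less than one quantization step.

## Numerical notes and edge cases

* Signals are stored in microvolts; the generator uses float32 (quantization
  and noise dwarf float32 rounding), EDF loads are float64.
* EDF+ writing uses 16-bit samples with per-channel symmetric physical
  ranges; the round-trip error bound is one quantization step.
* Identical config + seed reproduces every number bit-identically; child
  seeds are blake2-keyed on stable identifiers (subject id, test name).
* Degenerate inputs: flat ECG → empty peak series plus warning; empty
  epoch sets average to NaN with `valid=False`; zero-SD outlier input
  excludes nothing; an all-zero OLS outcome reports F = 0 explicitly.
* `rr_keep_mask` is monotone in the threshold and idempotent; epoch-order
  permutations change results only at float-summation order (≤ 1e-10 µV).

## Known limitations

Real EDF dialects beyond label-prefix/alias normalization may need an
annotation mapping (YAML) to translate site-specific strings.  The ASR
implementation removes flagged subspace components rather than regressing
them onto the clean subspace; on heavily contaminated, high-density
montages a reference ASR implementation would retain more neural signal.
LF/HF measures inherit all the usual caveats about sympathetic
interpretation and are reported as proxies only.
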