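# Methods

This note records the models, estimators and numerical choices behind
`pdfecg`, in the order the pipeline applies them.

## Page model and coordinate conventions

All geometry lives in native PDF user space: origin at the bottom-left,
y-up, units of 1/72 inch ("page units", pu). The expected page is a
GE/Marquette-style report: twelve 2.5 s strips in a 6×2 grid (columns
I–aVL and V1–V6, top to bottom), each lead drawn as one stroked polyline
with one vertex per sample. Chart calibration defaults to the universal
clinical standard — 25 mm/s, 10 mm/mV — with one vertex every 0.05 mm,
i.e. 500 Hz, and amplitudes quantized in 4.88 µV ADC units. All of these
are fields of `CalibrationParams`, overridable per document; the
constructor enforces the consistency identity
`sample_spacing_mm × sampling_rate_hz = mm_per_second` (0.05 × 500 = 25).

The PDF backend (`pdfecg._pdf`) implements exactly the subset such reports
use: `m/l/c/re/h` path construction, stroke/fill painting, `cm`
transforms, simple-font text operators, plain or FlateDecode streams.
Bezier segments are flattened at a 0.05 pu chord tolerance (report
generators emit polylines; curves are tolerated defensively). Object
extents are taken from the xref table and declared `/Length` values, never
by scanning for markers, because compressed stream bytes may contain any
pattern.

## Stroke classification

Strokes are partitioned into waveform / grid / calibration / other.
A waveform stroke needs ≥ 20 points, ≥ 90 % non-negative x-steps
(monotone-dominant progression) and y-standard deviation ≥ 0.1 pu; an
axis-aligned segment straight to within 0.5 pu is grid; an open
up–flat–down rectangular pulse 0.35–1.6 mV tall is a calibration mark.
Thresholds live in `ClassifierConfig`. Classification is a pure partition:
stroke count and identity are conserved.

## Layout detection

Columns are found by x-interval overlap union (fragments of one lead abut;
distinct columns are separated by a real gap), rows by clustering each
column's strokes on their isoelectric level with a 20 pu gap threshold.
Lead names come from label text spans when present (matched by proximity,
label sitting at/left of the strip start), else from the configured printed
order, column-major from the top. Fewer than 12 resolvable strips raises
`LayoutError` naming the missing leads. Strip boxes extend one strip
duration right of the leftmost stroke point and half a row pitch above and
below the baseline.

## Artifact resolution

*Lead assignment* is by **path membership**: each waveform stroke goes
wholly to the strip containing the majority of its points; exact ties break
toward the strip whose baseline is nearest the path's median y; strokes in
no strip are dropped with a warning (decorative ink exists on real pages).
This is what keeps a deep-S excursion with its own lead where per-point
bounding-box assignment (implemented as the deliberate baseline
`pdfecg.foil.naive_bbox_digitize`) grafts it onto the victim lead below.

*Text collisions* cannot contaminate a path-based extraction; the
`remove_text_collisions` pass only verifies that no glyph-outline stroke
was misclassified into a trace — any minority source path lying wholly
inside one text bbox (±1 pu) is stripped.

*Retrace resolution* collapses repeated x positions to their mean y and
sorts x strictly increasing (vector pens may revisit x).

*Baseline estimation* (`isoelectric_level`) is two-stage. Stage one:
histogram mode at 0.1 pu resolution, refined by the median within ±0.25 pu
of the modal bin — the flat PQ/TP segments dominate an ECG's amplitude
histogram. Stage one alone is biased upward by up to ~2 ADC quanta at fast
heart rates: a Gaussian-shaped P or T wave *lingers* just above the
baseline near its onset and offset (sample density at level u grows as the
local slope shrinks), piling mass right above zero. Stage two removes this:
only flat **runs** of ≥ 30 consecutive samples inside a noise-adaptive band
(4× a robust first-difference noise scale, floored at 2× the mode window)
are kept, with 5 samples trimmed from each run end, and their median is the
baseline. Wave tails cross the band briefly and never form a long run, so
only genuine isoelectric time survives; the residual bias is at most one
quantum. Baseline correction then translates the trace by a single
constant — shape is preserved exactly, and a lead drawn with a constant
offset (the third artifact) is re-referenced to its own isoelectric level.

## Calibration and resampling

`page_to_physical` is the exact affine map; its inverse is the renderer's.
Traces are linearly interpolated onto the uniform grid `t_k = k/fs`
(N = strip_seconds × fs samples) with edge-hold and no extrapolation; a
trace covering under 80 % of the strip raises `ShortStripError`.
Quantization rounds half-to-even; `|dequantize(quantize(v)) − v| ≤ 2.44 µV`
always. The filtering stack (0.5 Hz high-pass, 150 Hz low-pass clamped
below Nyquist, optional mains notch) is zero-phase (forward–backward
Butterworth) so fiducial timing is not skewed — and it is **off by default**
in the digitization path, because vendor pages render already-preprocessed
waveforms; it exists for noisy synthetic test signals. Records persist as a
CSV signal table plus a JSON provenance sidecar.

## Beat detection and delineation

R peaks: 5–30 Hz band-pass, squared derivative, 80 ms moving-window
integration, adaptive threshold at 35 % of the max envelope, ≥ 200 ms
refractory, with the apex refined to the raw extremum within ±60 ms.
Candidates within 100 ms of a strip end are rejected: a full QRS cannot be
contained there, and edge-truncated partial beats of the neighbouring cycle
otherwise register as extra complexes.

Delineation reads all landmark geometry off a copy smoothed with a
σ = 2-sample Gaussian; since smoothing a Gaussian wave adds exactly the
smoothing variance to its width, that inflation is subtracted back out of
every estimated width ("deconvolved"). The baseline is the isoelectric
mode, not the median (P/T waves skew the plain median by a few µV, which
shifts every half-max crossing). Q and S are the opposite-polarity extrema
within ±80 ms of R. Onsets/offsets are **half-maximum width
extrapolations**: σ = HWHM/1.177 from the crossing on the outward side,
onset = peak − 3σ (offset symmetric). For the isolated, symmetric P and T
waves the centre is re-estimated as the midpoint of the two half-max
crossings — a broad flat wave's argmax wanders several samples under noise,
and that error would be amplified ×1.5 into the extrapolated onset. A
5.5 %-of-max-slope threshold crossing is the fallback where no half-max
crossing exists (5.5 % is the fraction at which a Gaussian's slope sits at
its ±3σ point, keeping the two definitions consistent). P is the **last**
prominent peak in the [−300, −80] ms window before QRS onset and T the
**first** in [+80, +400] ms after QRS offset: the wave nearest the QRS is
the right one, and at fast rates the neighbouring beat's larger wave enters
the search window and would hijack a global-extremum rule. Waves below
their amplitude floor (25 µV for P/T, 20 µV for Q/S) or with windows
outside the strip are reported absent, never fabricated.

Global measures follow the 12-lead vendor convention: beats are matched
across leads by R-time within ±150 ms; per matched beat, QRS duration is
(max S offset over leads) − (min Q onset over leads) and PR is
(min QRS onset) − (min P onset); values are averaged over beats. Rate uses
the interval convention (n−1 intervals over the first-to-last R span =
60/RR); the literal count-over-span reading, which overestimates by
n/(n−1), is available as `rate_convention="literal_count"`.

## Alignment

Each trace contributes one designated beat — the R nearest the strip
centre. Rows are shifted by integer samples (2 ms granularity preserves
values exactly) so every designated R lands on the median R index; vacated
edges hold the edge value; columns covered by fewer than 95 % of rows are
cropped so one outlier shift cannot shrink the common window. The mean
signal vector is the column-wise mean.

## Evaluation

Bland–Altman: diffs = x − y, bias = mean, limits = bias ± 1.96·SD(ddof=1).
Pearson: product-moment r with t = r√((n−2)/(1−r²)) against the
t-distribution, two-sided, α = 0.05.

The split plan draws, per run, one uniformly random patient per class into
the test set (all their ECGs together); patient-level disjointness is
asserted on every run, not assumed. The classifier is a fresh RBF-kernel
SVM (C = 1) per run, with features z-scored on train-split statistics only.

Features are the twelve R-aligned leads, each cropped to a 700 ms window
centred on the common R column, decimated ×4 and concatenated
(≈ 1050 dims). The window matters: with full 2.5 s strips the positions of
*neighbouring* beats dominate the kernel, so heart rate — not morphology —
drives classification, and a patient whose rate happens to match another
class's is misassigned. The windowed aligned beat is precisely the object
the alignment step exists to produce.

One-vs-rest AUC is the **mean of per-run AUCs** on decision scores
(rank-based within each run; per-run score offsets cannot masquerade as
discrimination), with pooled-score AUC kept as a secondary field. The
chance-level reference permutes the per-ECG labels and averages 20
independent permutations of 10 runs each: a single permutation retains
chance correlations with the patient-cluster structure and its AUC
scatters far from 0.5. Calibration curves bin Platt probabilities into 10
equal-width bins. Confusion metrics are one-vs-rest
precision/sensitivity/specificity/F1; zero denominators yield 0 with a
flag.

## Synthetic data: what it emulates and what it does not

Each lead is a sum of Gaussian wave components (P, Q, R, S, T) repeated at
the programmed R-R interval, plus white noise (default σ = 10 µV — vendor
pages render already-denoised signals) and optional sinusoidal drift. The
Gaussian model was chosen over dynamical-system simulators because every
fiducial has a closed form: a wave's onset/offset is its centre ∓ 3σ, so
the programmed PR, QRS and rate are *exactly* recoverable from the truth
landmarks (ground-truth closure). Widths are tied to the programmed QRS
duration (σ_R = QRS/9, σ_Q = σ_S = QRS/18, Q and S centred 3σ inside the
onset/offset); σ_P = 10 ms, σ_T = 30 ms, T peaking 150 ms after QRS offset.
The first beat lands at max(0.3·RR, 0.36 s) so a full P–QRS–T fits; waves
truncated by the strip edge are marked absent in the truth. Infeasible
programmes (waves of consecutive beats overlapping) raise `ParamError`,
and the randomized-interval sampler rejection-samples until feasible.

The renderer draws one path per lead (a fragmented mode splits each lead
into ≥ 3 abutting paths to stress majority-vote assignment), quantizes
drawn amplitudes by default (a non-quantized mode exists because the
digitizer must not assume it), and injects the three artifacts on request:
the label moved onto the first QRS, a source lead re-synthesized with an S
wave deep enough to cross half the row pitch into the strip below (the
overlap is real signal, as on clinical pages), and a constant baseline
offset of the drawn path. A manifest records every path→lead mapping, the
exact layout and the artifact inventory, so round-trip oracles are exact.

The five class presets (ToF, PA, Fontan, ASD, Mustard) are **caricatures,
not clinical claims**: distinct per-lead amplitude signatures (e.g. tall
V1–V2 R for ToF, globally low voltages for Fontan, deep right-precordial S
for Mustard) with patient-level jitter (3 % amplitude CV; PR/QRS/rate SD
4 ms/3 ms/2 bpm) and record-level noise. They are built to be separable —
pairwise template distance exceeds 10× the jitter spread by construction —
so the classification experiment tests the *pipeline*, not cardiology.
Consequently, passing tests show that digitization, alignment, the split
protocol and the classifier plumbing are correct; they say nothing about
real-world diagnostic accuracy, where class overlap, rhythm variation,
pathology heterogeneity and electrode placement dominate.

## Problem sizes

The shipped experiments use 50 fixtures for round-trip and artifact
checks, 200 randomized ECGs for interval agreement, 40 traces for
alignment, and a 10-patients-per-class × 5-ECG cohort with 100
leave-out runs (plus 20×10 permuted-label runs) for classification —
desk-scale stand-ins for a clinical archive, chosen so the full suite and
the acceptance script each run in minutes on one CPU.

## Known limitations

- Raster-only pages are rejected (`RasterPageError`), by design: the method
  exists for vector pages and cannot improve pixel images.
- The PDF parser covers the report-generator subset, not arbitrary PDFs
  (no encryption, no Type 0 font metrics, no inline images).
- Layouts beyond a rows×columns grid of equal strips (rhythm strips,
  3×4-with-rhythm) are out of scope; `LayoutConfig` covers grid variants.
- QT/QTc, axis and fragmentation scoring are not measured.
- The 4 kHz pre-decimation stream cannot be reconstructed from a 500 Hz
  rendering; the package recovers what the page contains.
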