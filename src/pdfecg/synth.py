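"""Ground-truthed synthetic 12-lead ECGs and their vector-PDF renderings.

The beat model is a sum of Gaussian wave components (P, Q, R, S, T) repeated
at the programmed R-R interval.  Gaussians are chosen over a dynamical-system
simulator because every fiducial has a closed form: a wave's onset and
offset are its centre -+ 3 sigma, so the programmed PR interval, QRS
duration and rate are exactly recoverable from the analytic landmarks.
Realism is deliberately subordinate to testability — class presets are
caricatures of post-surgical morphology, not clinical claims.

The renderer emulates a GE/Marquette-style report page: twelve 2.5 s strips
in a 6x2 grid at 25 mm/s and 10 mm/mV, one polyline vertex every 0.05 mm
(500 Hz), amplitudes quantized in 4.88 uV steps, lead names as text.  Three
artifact types can be injected on demand: a lead-name label moved onto the
trace, a deep QRS excursion from one strip into the strip below, and a
constant vertical offset of a drawn lead.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from pdfecg._pdf.writer import PdfWriter, text_bbox
from pdfecg.calibrate import (
    LEAD_ORDER,
    CalibrationParams,
    DigitizedLead,
    ECGRecord,
    dequantize_amplitude,
    quantize_amplitude,
    record_to_csv,
)
from pdfecg.errors import ParamError
from pdfecg.fiducials import BeatFiducials, FiducialSet, IntervalMeasurements, Wave
from pdfecg.reconstruct import LeadLayout

__all__ = [
    "BeatModelParams",
    "ArtifactManifest",
    "SyntheticGroundTruth",
    "CLASS_LABELS",
    "class_preset",
    "jitter_params",
    "random_interval_params",
    "synthesize_ecg",
    "default_page_layout",
    "render_pdf",
    "generate_cohort",
]

CLASS_LABELS = ("ToF", "PA", "Fontan", "ASD", "Mustard")

# canonical wave amplitudes (mV) scaled per lead; sigma_p / sigma_t in ms
_BASE_AMPS = {"P": 0.15, "Q": -0.15, "R": 1.0, "S": -0.30, "T": 0.30}


@dataclass(frozen=True)
class BeatModelParams:
    """Programmed beat morphology and timing for one synthetic ECG."""

    rate_bpm: float = 75.0
    pr_ms: float = 160.0
    qrs_ms: float = 100.0
    lead_amplitudes: dict = None     # lead -> {wave -> mV}
    sigma_p_ms: float = 10.0
    sigma_t_ms: float = 30.0
    t_peak_after_qrs_ms: float = 150.0
    noise_sigma_uV: float = 10.0
    baseline_drift: tuple | None = None    # (amplitude mV, frequency Hz)
    first_beat_fraction: float = 0.3       # first R at max(this*RR, 0.36 s)

    def __post_init__(self):
        if self.lead_amplitudes is None:
            amps = {lead: dict(_BASE_AMPS) for lead in LEAD_ORDER}
            object.__setattr__(self, "lead_amplitudes", amps)
        if not 30 <= self.rate_bpm <= 250:
            raise ParamError(f"rate {self.rate_bpm} bpm out of range")
        if self.qrs_ms <= 0 or self.pr_ms <= 0:
            raise ParamError("intervals must be positive")
        if self.pr_ms < 6 * self.sigma_p_ms + 5:
            raise ParamError(
                f"PR {self.pr_ms} ms too short for P width sigma={self.sigma_p_ms} ms"
            )
        rr_ms = 60000.0 / self.rate_bpm
        t_end = self.qrs_ms / 2 + self.t_peak_after_qrs_ms + 3 * self.sigma_t_ms
        if t_end + self.pr_ms + 3 * self.sigma_p_ms > rr_ms:
            raise ParamError("waves of consecutive beats would overlap at this rate")

    # -- derived Gaussian components (centres relative to the R peak, ms) ----

    @property
    def sigma_q_ms(self) -> float:
        return self.qrs_ms / 18.0

    @property
    def sigma_r_ms(self) -> float:
        return self.qrs_ms / 9.0

    @property
    def sigma_s_ms(self) -> float:
        return self.qrs_ms / 18.0

    def components(self, lead: str) -> list:
        """(wave, amplitude mV, centre ms rel. R, sigma ms) for one lead."""
        a = self.lead_amplitudes[lead]
        qrs_on = -self.qrs_ms / 2.0
        qrs_off = +self.qrs_ms / 2.0
        return [
            ("P", a["P"], qrs_on - self.pr_ms + 3 * self.sigma_p_ms, self.sigma_p_ms),
            ("Q", a["Q"], qrs_on + 3 * self.sigma_q_ms, self.sigma_q_ms),
            ("R", a["R"], 0.0, self.sigma_r_ms),
            ("S", a["S"], qrs_off - 3 * self.sigma_s_ms, self.sigma_s_ms),
            ("T", a["T"], qrs_off + self.t_peak_after_qrs_ms, self.sigma_t_ms),
        ]


@dataclass(frozen=True)
class ArtifactManifest:
    """Which of the three rendering artifacts a fixture carries."""

    label_overlap: dict = field(default_factory=dict)      # lead -> label bbox
    cross_lead_overlap: tuple = ()    # ((source, victim, S amplitude mV), ...)
    baseline_shift_mm: dict = field(default_factory=dict)  # lead -> mm offset
    glyph_strokes: tuple = ()         # leads with an adversarial glyph path

    @property
    def any(self) -> bool:
        return bool(self.label_overlap or self.cross_lead_overlap
                    or self.baseline_shift_mm or self.glyph_strokes)


@dataclass
class SyntheticGroundTruth:
    record: ECGRecord
    fiducials: dict                   # lead -> FiducialSet (analytic truth)
    intervals: IntervalMeasurements
    manifest: ArtifactManifest
    layout: LeadLayout
    calib: CalibrationParams
    params: BeatModelParams
    class_label: str | None = None
    seed: int = 0


# ---------------------------------------------------------------------------
# synthesis

def _beat_times(params: BeatModelParams, strip_s: float) -> np.ndarray:
    rr = 60.0 / params.rate_bpm
    t0 = max(params.first_beat_fraction * rr, 0.36)
    times = []
    t = t0
    while t < strip_s:
        times.append(t)
        t += rr
    return np.asarray(times)


def synthesize_ecg(params: BeatModelParams, seed: int = 0,
                   calib: CalibrationParams | None = None,
                   class_label: str | None = None,
                   patient_id: str = "", record_id: str = ""
                   ) -> SyntheticGroundTruth:
    """Sample the Gaussian-sum beat model on the 500 Hz strip grid.

    The analytic fiducials (wave onset/peak/offset at centre -+ 3 sigma, in
    fractional sample units) and the programmed intervals are returned as
    ground truth alongside the noisy sampled record.
    """
    calib = calib or CalibrationParams()
    rng = np.random.default_rng(seed)
    fs = calib.sampling_rate_hz
    n = calib.n_samples
    t = np.arange(n) / fs
    beat_t = _beat_times(params, calib.strip_seconds)

    leads, fiducials = {}, {}
    for lead in LEAD_ORDER:
        comps = params.components(lead)
        v = np.zeros(n)
        for tb in beat_t:
            for _w, amp, c_ms, s_ms in comps:
                c = tb + c_ms / 1000.0
                s = s_ms / 1000.0
                v += amp * np.exp(-0.5 * ((t - c) / s) ** 2)
        if params.baseline_drift is not None:
            damp, dfreq = params.baseline_drift
            v += damp * np.sin(2 * np.pi * dfreq * t)
        v += rng.normal(0.0, params.noise_sigma_uV / 1000.0, size=n)
        leads[lead] = DigitizedLead(lead, v, fs)

        beats, r_idx = [], []
        for tb in beat_t:
            waves = {}
            for w, amp, c_ms, s_ms in comps:
                centre = (tb + c_ms / 1000.0) * fs
                onset = centre - 3 * s_ms / 1000.0 * fs
                offset = centre + 3 * s_ms / 1000.0 * fs
                if onset < 0 or offset > n - 1:
                    continue          # wave truncated by the strip: absent
                waves[w] = Wave(centre, onset, offset, amp)
            if "R" in waves:
                beats.append(BeatFiducials(waves))
                r_idx.append(int(round(tb * fs)))
        fiducials[lead] = FiducialSet(lead, fs, np.asarray(r_idx), tuple(beats))

    record = ECGRecord(leads, patient_id=patient_id, record_id=record_id)
    intervals = IntervalMeasurements(params.pr_ms, params.qrs_ms, params.rate_bpm)
    return SyntheticGroundTruth(
        record, fiducials, intervals, ArtifactManifest(),
        default_page_layout(calib), calib, params, class_label, seed,
    )


# ---------------------------------------------------------------------------
# class presets and parameter randomisation

# per-class interval programme and lead-scale signature; the precordial
# scale vector is what separates the classes geometrically
_PRESETS = {
    # right-ventricular dominance: tall R in V1-V2, small lateral leads
    "ToF":     dict(rate=82, pr=168, qrs=148,
                    scale=(0.7, 0.9, 0.8, 0.8, 0.6, 0.5,
                           1.9, 1.5, 0.9, 0.7, 0.6, 0.5), s_boost=1.6),
    # mid/late precordial emphasis with modest limb leads
    "PA":      dict(rate=88, pr=152, qrs=128,
                    scale=(0.6, 0.8, 0.7, 0.7, 0.5, 0.5,
                           0.8, 1.1, 1.5, 1.7, 1.5, 1.2), s_boost=1.0),
    # globally low voltages, slow rate
    "Fontan":  dict(rate=66, pr=188, qrs=104,
                    scale=(0.5, 0.6, 0.5, 0.5, 0.4, 0.4,
                           0.6, 0.6, 0.7, 0.6, 0.5, 0.5), s_boost=0.8),
    # inferior-limb emphasis, shallow S waves
    "ASD":     dict(rate=76, pr=176, qrs=96,
                    scale=(1.1, 1.5, 1.3, 1.4, 0.8, 0.6,
                           0.7, 0.8, 1.0, 1.2, 1.3, 1.2), s_boost=0.6),
    # deep right-precordial S waves after atrial switch
    "Mustard": dict(rate=72, pr=144, qrs=120,
                    scale=(0.9, 1.0, 1.0, 1.0, 0.8, 0.7,
                           1.3, 1.8, 1.5, 1.0, 0.8, 0.7), s_boost=2.4),
}


def class_preset(label: str) -> BeatModelParams:
    """Deterministic morphology template for one of the five diagnosis classes."""
    p = _PRESETS[label]    # unknown label -> KeyError, intentionally
    amps = {}
    for lead, sc in zip(LEAD_ORDER, p["scale"]):
        amps[lead] = {w: a * sc for w, a in _BASE_AMPS.items()}
        amps[lead]["S"] *= p["s_boost"]
    return BeatModelParams(rate_bpm=p["rate"], pr_ms=p["pr"], qrs_ms=p["qrs"],
                           lead_amplitudes=amps)


def jitter_params(params: BeatModelParams, rng: np.random.Generator,
                  amp_cv: float = 0.03, pr_sd_ms: float = 4.0,
                  qrs_sd_ms: float = 3.0, rate_sd_bpm: float = 2.0
                  ) -> BeatModelParams:
    """Patient-level variation on top of a template (amplitudes and timing)."""
    amps = {lead: {w: a * (1.0 + rng.normal(0, amp_cv))
                   for w, a in waves.items()}
            for lead, waves in params.lead_amplitudes.items()}
    return replace(params,
                   rate_bpm=float(np.clip(params.rate_bpm + rng.normal(0, rate_sd_bpm), 45, 115)),
                   pr_ms=float(np.clip(params.pr_ms + rng.normal(0, pr_sd_ms), 110, 230)),
                   qrs_ms=float(np.clip(params.qrs_ms + rng.normal(0, qrs_sd_ms), 70, 190)),
                   lead_amplitudes=amps)


def random_interval_params(rng: np.random.Generator) -> BeatModelParams:
    """Randomized PR/QRS/rate draw for interval-recovery validation.

    Wave shape is identical across leads up to a per-lead scale factor, so
    the cross-lead min/max in the global measures sees one consistent
    morphology — what a single heart actually produces.  Draws are rejected
    until the PR/QRS/rate combination admits non-overlapping beats (a long
    PR with a wide QRS at a fast rate is not a realisable rhythm).
    """
    for _ in range(200):
        pr = float(rng.uniform(120, 220))
        qrs = float(rng.uniform(80, 180))
        rate = float(rng.uniform(50, 110))
        scales = rng.uniform(0.7, 1.3, size=12)
        amps = {lead: {w: a * s for w, a in _BASE_AMPS.items()}
                for lead, s in zip(LEAD_ORDER, scales)}
        try:
            return BeatModelParams(rate_bpm=rate, pr_ms=pr, qrs_ms=qrs,
                                   lead_amplitudes=amps)
        except ParamError:
            continue
    raise ParamError("could not draw feasible interval parameters")


# ---------------------------------------------------------------------------
# page geometry and rendering

PAGE_W, PAGE_H = 595.0, 842.0
_COL_X = (70.0, 330.0)
_ROW_TOP_Y = 730.0
_ROW_PITCH = 70.0
LABEL_FONT = 8.0


def default_page_layout(calib: CalibrationParams | None = None,
                        baseline_shift_mm: dict | None = None) -> LeadLayout:
    """Nominal 6x2 grid; shifts move a lead's drawn baseline off its row."""
    calib = calib or CalibrationParams()
    shift = baseline_shift_mm or {}
    width = calib.strip_seconds * calib.page_units_per_second
    boxes, baselines, origins = {}, {}, {}
    for i, lead in enumerate(LEAD_ORDER):
        col, row = divmod(i, 6)
        x0 = _COL_X[col]
        y = _ROW_TOP_Y - row * _ROW_PITCH + shift.get(lead, 0.0) * calib.page_units_per_mm
        boxes[lead] = (x0, y - _ROW_PITCH / 2.0, x0 + width, y + _ROW_PITCH / 2.0)
        baselines[lead] = y
        origins[lead] = x0
    return LeadLayout(LEAD_ORDER, boxes, baselines, origins)


@dataclass(frozen=True)
class RenderOptions:
    quantize: bool = True            # snap drawn amplitudes to the ADC quantum
    draw_border: bool = True
    draw_labels: bool = True
    draw_grid: bool = False
    draw_cal_pulse: bool = False
    n_fragments: int = 1             # >= 3 exercises majority-vote assignment
    drop_leads: tuple = ()           # omit these paths (negative fixtures)
    labels_only: bool = False        # page with labels but no waveforms


def apply_artifacts(truth: SyntheticGroundTruth,
                    label_overlap: tuple = (),
                    cross_lead_overlap: tuple = (),
                    baseline_shift_mm: dict | None = None,
                    glyph_strokes: tuple = ()) -> SyntheticGroundTruth:
    """Prepare a truth object for artifact injection at render time.

    Cross-lead overlap is a property of the SIGNAL (a genuinely deep S wave),
    so the source lead is re-synthesized with its S amplitude boosted until
    the drawn excursion crosses into the strip below; the other two artifacts
    are pure rendering perturbations recorded in the manifest.
    """
    shift = dict(baseline_shift_mm or {})
    overl = []
    params = truth.params
    if cross_lead_overlap:
        amps = {k: dict(v) for k, v in params.lead_amplitudes.items()}
        # S deep enough to cross half the row pitch plus a margin
        excursion_mV = (_ROW_PITCH / 2.0 + 12.0) / truth.calib.page_units_per_mV
        for source, victim in cross_lead_overlap:
            amps[source]["S"] = -excursion_mV
            overl.append((source, victim, -excursion_mV))
        params = replace(params, lead_amplitudes=amps)
        truth = synthesize_ecg(params, seed=truth.seed, calib=truth.calib,
                               class_label=truth.class_label,
                               patient_id=truth.record.patient_id,
                               record_id=truth.record.record_id)
    manifest = ArtifactManifest(
        label_overlap={lead: None for lead in label_overlap},
        cross_lead_overlap=tuple(overl),
        baseline_shift_mm=shift,
        glyph_strokes=tuple(glyph_strokes),
    )
    truth.manifest = manifest
    truth.layout = default_page_layout(truth.calib, shift)
    return truth


def render_pdf(truth: SyntheticGroundTruth, path=None,
               options: RenderOptions | None = None) -> tuple[bytes, dict]:
    """Draw the truth record as a vector PDF page.

    Each lead is one stroked polyline (or ``n_fragments`` consecutive path
    objects) with one vertex per sample at 0.05 mm spacing.  Returns the PDF
    bytes and a manifest dict mapping every path id to its lead, plus the
    exact layout, for round-trip oracles.  ``path`` may name a .pdf file to
    write; a ``.manifest.json`` sidecar is written next to it.
    """
    opt = options or RenderOptions()
    calib = truth.calib
    layout = truth.layout
    writer = PdfWriter(compress=True)
    page = writer.new_page(PAGE_W, PAGE_H)
    path_map: dict[str, str] = {}

    if opt.draw_border:
        page.add_rect(40, 320, 520, 450, stroke_width=1.0)

    if opt.draw_grid:
        step = 5.0 * calib.page_units_per_mm
        x = 45.0
        while x < 560:
            page.add_polyline([(x, 330), (x, 760)], stroke_width=0.2)
            x += step
        y = 330.0
        while y < 760:
            page.add_polyline([(45, y), (555, y)], stroke_width=0.2)
            y += step

    dx = calib.sample_spacing_mm * calib.page_units_per_mm
    pu_mV = calib.page_units_per_mV

    # label anchors are needed before the lead loop: the adversarial glyph
    # stroke is drawn inside its lead's label bbox
    label_anchor: dict[str, tuple] = {}
    label_positions: dict[str, tuple] = {}
    for lead in LEAD_ORDER:
        x0 = layout.time_origin_x[lead]
        b = layout.baseline_y[lead]
        if lead in truth.manifest.label_overlap:
            # drop the label onto the first QRS region of the trace
            beat_t = _beat_times(truth.params, calib.strip_seconds)
            lx = x0 + beat_t[0] * calib.page_units_per_second - 5
            ly = b + 2
        else:
            lx, ly = x0 - 22, b + 4
        label_anchor[lead] = (lx, ly)
        label_positions[lead] = text_bbox(lead, lx, ly, LABEL_FONT)

    for lead in LEAD_ORDER:
        if lead in opt.drop_leads or opt.labels_only:
            continue
        v = truth.record.leads[lead].samples
        if opt.quantize:
            v = dequantize_amplitude(quantize_amplitude(v, calib), calib)
        x0 = layout.time_origin_x[lead]
        b = layout.baseline_y[lead]
        xs = x0 + np.arange(v.size) * dx
        ys = b + v * pu_mV
        pts = np.column_stack([xs, ys])

        if opt.draw_cal_pulse:
            h = 1.0 * pu_mV
            page.add_polyline([(x0 - 14, b), (x0 - 14, b + h),
                               (x0 - 4, b + h), (x0 - 4, b)], stroke_width=0.8)

        nfrag = max(opt.n_fragments, 1)
        bounds = np.linspace(0, v.size, nfrag + 1).astype(int)
        for a, z in zip(bounds[:-1], bounds[1:]):
            z = min(z + 1, v.size)          # share one vertex so no gap
            idx = page.add_polyline(pts[a:z], stroke_width=0.8)
            path_map[f"p{idx}.0"] = lead

        if lead in truth.manifest.glyph_strokes:
            # adversarial: a glyph-like zigzag wholly inside the label bbox
            lx, ly = label_anchor[lead]
            zz = [(lx + 1 + 0.3 * k, ly + 1 + (3 if k % 2 else 0))
                  for k in range(24)]
            idx = page.add_polyline(zz, stroke_width=0.6)
            path_map[f"p{idx}.0"] = f"__glyph_{lead}"

    if opt.draw_labels:
        for lead in LEAD_ORDER:
            lx, ly = label_anchor[lead]
            page.add_text(lead, lx, ly, LABEL_FONT)

    data = writer.tobytes()
    manifest = {
        "path_map": path_map,
        "n_waveform_paths": sum(1 for v in path_map.values()
                                if not v.startswith("__glyph")),
        "layout": {
            "strip_boxes": {k: list(v) for k, v in layout.strip_boxes.items()},
            "baseline_y": dict(layout.baseline_y),
            "time_origin_x": dict(layout.time_origin_x),
        },
        "labels": ({k: list(v) for k, v in label_positions.items()}
                   if opt.draw_labels else {}),
        "artifacts": {
            "label_overlap": sorted(truth.manifest.label_overlap),
            "cross_lead_overlap": [list(t) for t in truth.manifest.cross_lead_overlap],
            "baseline_shift_mm": dict(truth.manifest.baseline_shift_mm),
            "glyph_strokes": list(truth.manifest.glyph_strokes),
        },
        "quantized": opt.quantize,
        "class_label": truth.class_label,
        "patient_id": truth.record.patient_id,
        "record_id": truth.record.record_id,
        "intervals": {"pr_ms": truth.intervals.pr_ms,
                      "qrs_ms": truth.intervals.qrs_ms,
                      "rate_bpm": truth.intervals.rate_bpm},
    }
    if path is not None:
        path = Path(path)
        path.write_bytes(data)
        with open(path.with_suffix(".manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=1)
    return data, manifest


# ---------------------------------------------------------------------------
# cohort generation

def generate_cohort(n_patients_per_class: int, ecgs_per_patient: int,
                    master_seed: int, out_dir,
                    class_labels: tuple = CLASS_LABELS,
                    write_truth_csv: bool = True) -> "Path":
    """Write a desk-scale fixture cohort: PDFs, truth sidecars and an index.

    Patient identity = one jittered preset; each of the patient's ECGs adds
    record-level noise (fresh seed) on the same morphology.  The whole tree
    is a pure function of ``master_seed`` and the counts.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(master_seed)
    rows = []
    for ci, label in enumerate(class_labels):
        for pi in range(n_patients_per_class):
            patient_id = f"{label}-{pi:03d}"
            p_rng = np.random.default_rng(master_seed + 1000 * ci + pi + 1)
            params = jitter_params(class_preset(label), p_rng)
            for ei in range(ecgs_per_patient):
                record_id = f"{patient_id}-e{ei}"
                seed = int(p_rng.integers(2 ** 31 - 1))
                truth = synthesize_ecg(params, seed=seed, class_label=label,
                                       patient_id=patient_id, record_id=record_id)
                pdf_path = out / f"{record_id}.pdf"
                render_pdf(truth, pdf_path)
                if write_truth_csv:
                    record_to_csv(truth.record, out / f"{record_id}.truth.csv")
                rows.append({"record_id": record_id, "patient_id": patient_id,
                             "class_label": label, "pdf": pdf_path.name,
                             "seed": seed})
    index = out / "index.csv"
    with open(index, "w", newline="") as fh:
        w = csv.DictWriter(fh, fieldnames=list(rows[0].keys()))
        w.writeheader()
        w.writerows(rows)
    _ = rng
    return index
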