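"""End-to-end digitization: PDF page -> calibrated 12-lead record."""

from __future__ import annotations

import re

from pdfecg.calibrate import (
    CalibrationParams,
    ECGRecord,
    FilterSpec,
    filter_signal,
    page_to_physical,
    resample_uniform,
)
from pdfecg.graphics import ClassifierConfig, classify_strokes, extract_page_graphics
from pdfecg.reconstruct import LayoutConfig, detect_layout, reconstruct_leads

__all__ = ["digitize_page", "parse_vendor_measurements"]

_VENDOR_RE = {
    "pr_ms": re.compile(r"\bPR\s*(?:interval)?\s*[:=]?\s*(\d{2,3})\s*ms", re.I),
    "qrs_ms": re.compile(r"\bQRS\s*(?:duration)?\s*[:=]?\s*(\d{2,3})\s*ms", re.I),
    "rate_bpm": re.compile(r"\b(?:vent(?:ricular)?\.?\s*rate|HR)\s*[:=]?\s*(\d{2,3})", re.I),
}


def parse_vendor_measurements(texts) -> dict | None:
    """Pull PR/QRS/rate numbers out of page annotation text, when printed."""
    joined = "  ".join(t.text for t in texts)
    found = {}
    for key, rx in _VENDOR_RE.items():
        m = rx.search(joined)
        if m:
            found[key] = float(m.group(1))
    return found or None


def digitize_page(pdf_source, page_index: int = 0,
                  calib: CalibrationParams | None = None,
                  layout_config: LayoutConfig | None = None,
                  classifier: ClassifierConfig | None = None,
                  filter_spec: FilterSpec | None = None,
                  patient_id: str = "", record_id: str = "") -> ECGRecord:
    """Digitize one vector-PDF ECG page into a calibrated record.

    Filtering is OFF unless a :class:`FilterSpec` is passed: vendor pages
    render already-preprocessed waveforms, and re-filtering would only blur
    them.  Pass a spec when digitizing noisy synthetic test pages.
    """
    calib = calib or CalibrationParams()
    cfg = layout_config or LayoutConfig(calib=calib)
    page = extract_page_graphics(pdf_source, page_index)
    page = classify_strokes(page, classifier)
    layout = detect_layout(page, cfg)
    traces = reconstruct_leads(page, layout, cfg)

    leads = {}
    for name, trace in traces.items():
        t, v = page_to_physical(trace.points[:, 0], trace.points[:, 1],
                                layout.baseline_y[name],
                                layout.time_origin_x[name], calib)
        lead = resample_uniform(t, v, calib, lead_name=name)
        if filter_spec is not None:
            lead = filter_signal(lead, filter_spec)
        leads[name] = lead

    return ECGRecord(leads, patient_id=patient_id, record_id=record_id,
                     vendor_measurements=parse_vendor_measurements(page.texts))
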