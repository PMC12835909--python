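"""Deliberately naive bounding-box digitizer used as a comparison baseline.

This mimics what pixel-oriented tools effectively do: every drawn point is
attributed to whichever strip box contains it, regardless of which path it
came from.  A tall QRS excursing from one strip into the one below is
therefore cut off its own lead and grafted onto the victim — exactly the
failure mode that path-membership assignment avoids.  It exists so tests can
demonstrate that the path-based mechanism, not the surrounding plumbing, is
what corrects cross-lead overlap.
"""

from __future__ import annotations

import numpy as np

from pdfecg.calibrate import (
    CalibrationParams,
    ECGRecord,
    page_to_physical,
    resample_uniform,
)
from pdfecg.errors import LayoutError
from pdfecg.graphics import ClassifierConfig, classify_strokes, extract_page_graphics
from pdfecg.reconstruct import (
    LayoutConfig,
    LeadTrace,
    correct_baseline_offset,
    detect_layout,
    resolve_retrace,
)

__all__ = ["naive_bbox_digitize"]


def naive_bbox_digitize(pdf_source, page_index: int = 0,
                        calib: CalibrationParams | None = None) -> ECGRecord:
    """Digitize by per-point box membership (no path identity)."""
    calib = calib or CalibrationParams()
    cfg = LayoutConfig(calib=calib)
    page = classify_strokes(extract_page_graphics(pdf_source, page_index),
                            ClassifierConfig())
    layout = detect_layout(page, cfg)

    names = list(layout.strip_boxes)
    boxes = np.array([layout.strip_boxes[n] for n in names])
    buckets: dict[str, list] = {n: [] for n in names}
    for stroke in page.waveform_strokes():
        pts = stroke.points
        inside = ((pts[:, 0:1] >= boxes[:, 0]) & (pts[:, 0:1] <= boxes[:, 2])
                  & (pts[:, 1:2] >= boxes[:, 1]) & (pts[:, 1:2] <= boxes[:, 3]))
        owner = np.where(inside.any(axis=1), inside.argmax(axis=1), -1)
        for k, name in enumerate(names):
            sel = pts[owner == k]
            if sel.size:
                buckets[name].append(sel)

    leads = {}
    for name in names:
        if not buckets[name]:
            raise LayoutError(f"no points fell into strip {name}", missing=(name,))
        pts = np.vstack(buckets[name])
        trace = resolve_retrace(LeadTrace(name, pts, ("naive",)))
        trace = correct_baseline_offset(trace, layout)
        t, v = page_to_physical(trace.points[:, 0], trace.points[:, 1],
                                layout.baseline_y[name],
                                layout.time_origin_x[name], calib)
        leads[name] = resample_uniform(t, v, calib, lead_name=name)
    return ECGRecord(leads)
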