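"""Page-level graphics extraction and stroke classification.

A GE/Marquette-style ECG report page is a set of stroked vector paths (the
twelve waveforms, possibly a border, a background grid and per-strip
calibration pulses) plus text annotations (lead names, notes).  This module
turns one PDF page into a :class:`PageGraphics` container and labels each
stroke as waveform / grid / calibration / other before any lead logic runs.

Coordinates are y-up page units (1/72 inch), the native PDF convention; the
reader guarantees this, so ingesting a page twice is exactly reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum

import numpy as np

from pdfecg._pdf import reader as _reader
from pdfecg._pdf.reader import read_pages, require_vector_page

__all__ = [
    "StrokeKind",
    "VectorStroke",
    "TextSpan",
    "PageGraphics",
    "ClassifierConfig",
    "extract_page_graphics",
    "classify_strokes",
]


class StrokeKind(str, Enum):
    UNCLASSIFIED = "unclassified"
    WAVEFORM = "waveform"
    GRID = "grid"
    CALIBRATION = "calibration"
    OTHER = "other"


@dataclass(frozen=True)
class VectorStroke:
    """One painted subpath with provenance back to its PDF path object."""

    points: np.ndarray              # (n, 2) y-up page units, drawing order
    path_id: str                    # stable within the page, e.g. "p12.0"
    width: float
    kind: StrokeKind = StrokeKind.UNCLASSIFIED

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[0] < 2 or pts.shape[1] != 2:
            raise ValueError("stroke needs an (n>=2, 2) point array")
        if not np.all(np.isfinite(pts)):
            raise ValueError("stroke contains non-finite coordinates")
        object.__setattr__(self, "points", pts)

    @property
    def n_points(self) -> int:
        return self.points.shape[0]


@dataclass(frozen=True)
class TextSpan:
    text: str
    bbox: tuple[float, float, float, float]   # (x0, y0, x1, y1)
    font_size: float

    def __post_init__(self):
        x0, y0, x1, y1 = self.bbox
        if not (x1 > x0 and y1 > y0):
            raise ValueError("degenerate text bbox")
        if not self.text:
            raise ValueError("empty text span")

    @property
    def center(self) -> tuple[float, float]:
        x0, y0, x1, y1 = self.bbox
        return ((x0 + x1) / 2.0, (y0 + y1) / 2.0)


@dataclass(frozen=True)
class PageGraphics:
    page_width: float
    page_height: float
    strokes: tuple[VectorStroke, ...] = ()
    texts: tuple[TextSpan, ...] = ()

    def waveform_strokes(self) -> tuple[VectorStroke, ...]:
        return tuple(s for s in self.strokes if s.kind is StrokeKind.WAVEFORM)


@dataclass(frozen=True)
class ClassifierConfig:
    """Thresholds for kind assignment; defaults suit clinical report geometry."""

    min_waveform_points: int = 20        # fewer points can't carry a 2.5 s strip
    min_waveform_y_std: float = 0.1      # page units; flat rules out a waveform
    monotone_x_fraction: float = 0.9     # share of non-negative x steps required
    grid_straightness_tol: float = 0.5   # page units from an axis-aligned line
    cal_pulse_max_points: int = 12
    cal_pulse_min_height: float = 10.0   # ~0.35 mV at 10 mm/mV; pulses are 1 mV
    cal_pulse_max_height: float = 45.0   # ~1.6 mV; anything taller is no pulse


def extract_page_graphics(pdf_source, page_index: int = 0) -> PageGraphics:
    """Read one page of a vector-PDF document into a :class:`PageGraphics`.

    ``pdf_source`` may be a filesystem path or raw PDF bytes.  Raises
    :class:`~pdfecg.errors.DocumentError` for corrupt/encrypted input and
    :class:`~pdfecg.errors.RasterPageError` when the page holds only a pixel
    image of the ECG.
    """
    pages = read_pages(pdf_source)
    if not 0 <= page_index < len(pages):
        raise IndexError(f"page {page_index} out of range (document has {len(pages)})")
    raw = require_vector_page(pages[page_index])

    strokes = tuple(
        VectorStroke(p.points, f"p{p.path_index}.{p.subpath_index}", p.stroke_width)
        for p in raw.paths
    )
    texts = tuple(
        TextSpan(t.text, t.bbox, t.size) for t in raw.texts
    )
    return PageGraphics(raw.width, raw.height, strokes, texts)


# ---------------------------------------------------------------------------
# classification

def _is_axis_aligned_line(pts: np.ndarray, tol: float) -> bool:
    return (np.ptp(pts[:, 0]) <= tol) or (np.ptp(pts[:, 1]) <= tol)


def _is_calibration_pulse(pts: np.ndarray, cfg: ClassifierConfig) -> bool:
    """Rectangular 1 mV pulse: axis-aligned segments, two y plateaus, short x span."""
    if pts.shape[0] > cfg.cal_pulse_max_points or pts.shape[0] < 4:
        return False
    if np.allclose(pts[0], pts[-1]):          # closed shape = border/box, not a pulse
        return False
    d = np.diff(pts, axis=0)
    axis_aligned = (np.abs(d[:, 0]) <= 0.25) | (np.abs(d[:, 1]) <= 0.25)
    if not np.all(axis_aligned):
        return False
    height = np.ptp(pts[:, 1])
    if not cfg.cal_pulse_min_height <= height <= cfg.cal_pulse_max_height:
        return False
    # up / flat / down signature in y
    dy = d[:, 1][np.abs(d[:, 1]) > 0.25]
    return len(dy) >= 2 and dy[0] > 0 and dy[-1] < 0


def _is_waveform(pts: np.ndarray, cfg: ClassifierConfig) -> bool:
    if pts.shape[0] < cfg.min_waveform_points:
        return False
    if float(np.std(pts[:, 1])) < cfg.min_waveform_y_std:
        return False
    dx = np.diff(pts[:, 0])
    if dx.size == 0:
        return False
    return float(np.mean(dx >= 0)) >= cfg.monotone_x_fraction


def classify_strokes(page: PageGraphics, hints: ClassifierConfig | None = None) -> PageGraphics:
    """Assign a :class:`StrokeKind` to every stroke; a pure partition.

    Order of tests matters: the calibration-pulse signature is checked before
    the generic waveform test (a pulse is monotone in x too), and straight
    axis-aligned segments become grid before anything else.
    """
    cfg = hints or ClassifierConfig()
    out = []
    for s in page.strokes:
        pts = s.points
        if _is_axis_aligned_line(pts, cfg.grid_straightness_tol):
            kind = StrokeKind.GRID
        elif _is_calibration_pulse(pts, cfg):
            kind = StrokeKind.CALIBRATION
        elif _is_waveform(pts, cfg):
            kind = StrokeKind.WAVEFORM
        else:
            kind = StrokeKind.OTHER
        out.append(replace(s, kind=kind))
    return PageGraphics(page.page_width, page.page_height, tuple(out), page.texts)
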