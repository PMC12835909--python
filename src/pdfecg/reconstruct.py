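"""Lead layout detection and artifact-robust trace reconstruction.

The printed page holds twelve 2.5 s strips in a 6x2 grid.  Three artifacts
routinely break naive pixel- or bbox-based digitizers:

* lead-name text drawn over the first QRS complex,
* a large QRS from one strip excursing into the strip printed below it,
* a whole lead drawn with a constant vertical offset from its nominal row.

Because every lead is stored as its own vector path, all three can be
resolved geometrically: a path belongs wholly to the strip that contains the
majority of its points (so an excursion into a neighbour stays with its
lead), text never contaminates a path in the first place, and a constant
offset moves the path's isoelectric mode along with it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from pdfecg.calibrate import LEAD_ORDER, CalibrationParams
from pdfecg.errors import LayoutError
from pdfecg.graphics import PageGraphics, StrokeKind, TextSpan, VectorStroke

__all__ = [
    "LayoutConfig",
    "LeadLayout",
    "LeadTrace",
    "detect_layout",
    "assign_strokes_to_leads",
    "build_trace",
    "remove_text_collisions",
    "resolve_retrace",
    "correct_baseline_offset",
    "isoelectric_level",
    "reconstruct_leads",
]


@dataclass(frozen=True)
class LayoutConfig:
    lead_order: tuple = LEAD_ORDER
    n_rows: int = 6
    n_cols: int = 2
    calib: CalibrationParams = field(default_factory=CalibrationParams)
    row_gap_min: float = 20.0      # page units; baseline gap that separates rows
    col_gap_min: float = 30.0      # page units; x gap that separates columns


@dataclass(frozen=True)
class LeadLayout:
    """Strip geometry for all 12 leads, in page units."""

    lead_order: tuple
    strip_boxes: dict               # name -> (x0, y0, x1, y1)
    baseline_y: dict                # name -> isoelectric y of the drawn trace
    time_origin_x: dict             # name -> x of t = 0

    def strip_of_point(self, x: float, y: float) -> str | None:
        for name, (x0, y0, x1, y1) in self.strip_boxes.items():
            if x0 <= x <= x1 and y0 <= y <= y1:
                return name
        return None


@dataclass(frozen=True)
class LeadTrace:
    """Page-coordinate point sequence attributed to one lead."""

    lead_name: str
    points: np.ndarray                   # (n, 2)
    source_path_ids: tuple               # distinct contributing path ids
    point_path_ids: np.ndarray = None    # per-point provenance (object array)

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float)
        object.__setattr__(self, "points", pts)
        if self.point_path_ids is None:
            ids = np.array([""] * pts.shape[0], dtype=object)
            object.__setattr__(self, "point_path_ids", ids)


# ---------------------------------------------------------------------------
# baseline estimation

def isoelectric_level(y: np.ndarray, mode_window: float = 0.25,
                      bin_width: float = 0.1, min_run: int = 30,
                      run_trim: int = 5) -> float:
    """Isoelectric (baseline) level of a trace's y coordinates.

    Two stages.  First a histogram mode at ``bin_width`` resolution, refined
    by the median within ``mode_window`` of the modal bin — the flat PQ/TP
    segments dominate an ECG's amplitude histogram, so this tracks the drawn
    baseline even under large QRS excursions or a DC shift.  The mode alone,
    however, is pulled upward by wave *tails*: a Gaussian-shaped P or T wave
    lingers just above the baseline near its onset and offset, piling sample
    density right above zero.  The second stage removes that bias by keeping
    only long flat runs — segments of at least ``min_run`` consecutive
    samples inside a noise-adaptive band around the first estimate, with
    ``run_trim`` samples shaved off each end — and taking their median.
    Wave tails pass through the band briefly and never form a long run, so
    only genuine isoelectric time survives.

    ``y`` must be in drawing order (monotone time).  Units are whatever the
    caller uses; ``mode_window``/``bin_width`` scale with them.
    """
    y = np.asarray(y, dtype=float)
    lo, hi = y.min(), y.max()
    if hi - lo < bin_width:
        return float(np.median(y))
    nbins = max(int(np.ceil((hi - lo) / bin_width)), 1)
    counts, edges = np.histogram(y, bins=nbins)
    c = 0.5 * (edges[np.argmax(counts)] + edges[np.argmax(counts) + 1])
    window = y[np.abs(y - c) <= mode_window]
    c = float(np.median(window)) if window.size else float(c)

    # noise scale from first differences (robust, wave slopes are sparse)
    sigma_n = 1.4826 * float(np.median(np.abs(np.diff(y)))) / np.sqrt(2.0)
    band = max(4.0 * sigma_n, 2.0 * mode_window)
    flat = np.abs(y - c) <= band
    vals = []
    i, n = 0, y.size
    while i < n:
        if flat[i]:
            j = i
            while j < n and flat[j]:
                j += 1
            if j - i >= min_run:
                vals.append(y[i + run_trim:j - run_trim])
            i = j
        else:
            i += 1
    if not vals:
        return c
    return float(np.median(np.concatenate(vals)))


# ---------------------------------------------------------------------------
# layout detection

def _cluster_1d(values: np.ndarray, gap: float) -> list[np.ndarray]:
    """Indices of `values` grouped so consecutive sorted members differ < gap."""
    order = np.argsort(values)
    groups, current = [], [order[0]]
    for i in order[1:]:
        if values[i] - values[current[-1]] < gap:
            current.append(i)
        else:
            groups.append(np.array(current))
            current = [i]
    groups.append(np.array(current))
    return groups


def _lead_name_texts(page: PageGraphics, names: tuple) -> dict:
    out = {}
    for t in page.texts:
        key = t.text.strip()
        if key in names and key not in out:
            out[key] = t
    return out


def detect_layout(page: PageGraphics, config: LayoutConfig | None = None) -> LeadLayout:
    """Infer the 6x2 strip grid from the classified page.

    Waveform strokes are clustered into columns (by x origin) and rows (by
    their isoelectric y).  Lead names come from label text spans when present,
    falling back to the configured printed order, column-major from the top.
    Raises :class:`LayoutError`, listing the unresolvable leads, when fewer
    than 12 strips emerge.
    """
    cfg = config or LayoutConfig()
    waves = page.waveform_strokes()
    if not waves:
        raise LayoutError("page has no waveform strokes", missing=cfg.lead_order)

    # columns by x-interval overlap: fragments of one lead abut each other,
    # while distinct columns are separated by a real horizontal gap
    intervals = np.array([[s.points[:, 0].min(), s.points[:, 0].max()]
                          for s in waves])
    order = np.argsort(intervals[:, 0])
    col_groups: list[np.ndarray] = []
    current = [order[0]]
    reach = intervals[order[0], 1]
    for i in order[1:]:
        if intervals[i, 0] <= reach + cfg.col_gap_min:
            current.append(i)
            reach = max(reach, intervals[i, 1])
        else:
            col_groups.append(np.array(current))
            current, reach = [i], intervals[i, 1]
    col_groups.append(np.array(current))

    # split each column into rows by baseline level; fragments of one lead merge
    cells: list[tuple[int, int, list[VectorStroke]]] = []   # (col, row, strokes)
    for ci, idx in enumerate(col_groups):
        strokes = [waves[i] for i in idx]
        iso = np.array([isoelectric_level(s.points[:, 1]) for s in strokes])
        row_groups = _cluster_1d(iso, cfg.row_gap_min)
        # top row first: descending y
        row_groups.sort(key=lambda g: -iso[g].mean())
        for ri, g in enumerate(row_groups):
            cells.append((ci, ri, [strokes[i] for i in g]))

    labels = _lead_name_texts(page, cfg.lead_order)

    # name each cell: nearest lead-name label, else printed order
    named: dict[str, list[VectorStroke]] = {}
    cell_iso: dict[str, float] = {}
    for ci, ri, strokes in cells:
        pts = np.vstack([s.points for s in strokes])
        iso = isoelectric_level(pts[:, 1])
        x0 = pts[:, 0].min()
        name = None
        if labels:
            best, best_d = None, np.inf
            for lname, span in labels.items():
                lx, ly = span.center
                if lx > x0 + 30:      # label sits at/left of the strip start
                    continue
                d = abs(ly - iso) + 0.1 * abs(lx - x0)
                if d < best_d:
                    best, best_d = lname, d
            name = best
        if name is None or name in named:
            k = ci * cfg.n_rows + ri
            name = cfg.lead_order[k] if k < len(cfg.lead_order) else f"cell{ci}.{ri}"
        named[name] = strokes
        cell_iso[name] = iso

    missing = tuple(n for n in cfg.lead_order if n not in named)
    if missing:
        raise LayoutError(f"could not resolve leads: {', '.join(missing)}",
                          missing=missing)

    # strip boxes: x from origin + strip duration; y midway between neighbours
    pu_per_s = cfg.calib.page_units_per_second
    width = cfg.calib.strip_seconds * pu_per_s
    boxes, baselines, origins = {}, {}, {}
    # row pitch from baseline gaps (two columns share the same row grid, so
    # near-equal baselines across columns are excluded by the gap threshold)
    iso_vals = np.array([cell_iso[n] for n in named])
    gaps = np.abs(np.diff(np.sort(iso_vals)))
    gaps = gaps[gaps > cfg.row_gap_min]
    pitch = float(np.median(gaps)) if gaps.size else 60.0

    for name, strokes in named.items():
        pts = np.vstack([s.points for s in strokes])
        x0 = float(pts[:, 0].min())
        iso = cell_iso[name]
        boxes[name] = (x0, iso - pitch / 2.0, x0 + width, iso + pitch / 2.0)
        baselines[name] = iso
        origins[name] = x0
    return LeadLayout(cfg.lead_order, boxes, baselines, origins)


# ---------------------------------------------------------------------------
# stroke -> lead assignment (path-membership majority vote)

def assign_strokes_to_leads(page: PageGraphics, layout: LeadLayout
                            ) -> tuple[dict, list]:
    """Assign each waveform stroke wholly to one lead by majority membership.

    A path with most of its points inside strip k is lead k even where it
    excurses into a neighbouring strip — this is what keeps a tall QRS with
    its own lead instead of splitting it at the box edge.  Exact ties go to
    the strip whose baseline is nearest the path's median y.  Strokes inside
    no strip are dropped with a warning.

    Returns ``(mapping lead -> [strokes], dropped strokes)``.
    """
    names = list(layout.strip_boxes)
    boxes = np.array([layout.strip_boxes[n] for n in names])   # (L, 4)
    mapping: dict[str, list] = {n: [] for n in names}
    dropped = []
    for stroke in page.waveform_strokes():
        pts = stroke.points
        inside = ((pts[:, 0:1] >= boxes[:, 0]) & (pts[:, 0:1] <= boxes[:, 2])
                  & (pts[:, 1:2] >= boxes[:, 1]) & (pts[:, 1:2] <= boxes[:, 3]))
        counts = inside.sum(axis=0)
        if counts.max() == 0:
            warnings.warn(f"stroke {stroke.path_id} lies in no strip; dropped")
            dropped.append(stroke)
            continue
        winners = np.flatnonzero(counts == counts.max())
        if winners.size > 1:
            med_y = float(np.median(pts[:, 1]))
            winners = sorted(
                winners, key=lambda i: abs(layout.baseline_y[names[i]] - med_y))
        mapping[names[winners[0]]].append(stroke)
    return mapping, dropped


def build_trace(lead_name: str, strokes) -> LeadTrace:
    """Concatenate a lead's strokes into one trace with per-point provenance."""
    pts = np.vstack([s.points for s in strokes])
    ids = np.concatenate([
        np.array([s.path_id] * s.n_points, dtype=object) for s in strokes])
    return LeadTrace(lead_name, pts, tuple(s.path_id for s in strokes), ids)


# ---------------------------------------------------------------------------
# artifact resolution on a single trace

def remove_text_collisions(trace: LeadTrace, texts, max_glyph_fraction: float = 0.2
                           ) -> LeadTrace:
    """Strip glyph-derived points that were misclassified into the trace.

    Path-based extraction means label ink normally never touches a waveform
    path, so this is a verification pass: any minority source path of the
    trace whose points sit entirely inside one text bbox is a stray glyph
    outline and is removed.  A trace with no such path is returned unchanged.
    """
    if trace.points.shape[0] == 0 or not texts:
        return trace
    suspect_ids = []
    for pid in trace.source_path_ids:
        mask = trace.point_path_ids == pid
        n = int(mask.sum())
        if n == 0 or n > max_glyph_fraction * trace.points.shape[0]:
            continue
        pts = trace.points[mask]
        for span in texts:
            x0, y0, x1, y1 = span.bbox
            pad = 1.0
            if (np.all((pts[:, 0] >= x0 - pad) & (pts[:, 0] <= x1 + pad)
                       & (pts[:, 1] >= y0 - pad) & (pts[:, 1] <= y1 + pad))):
                suspect_ids.append(pid)
                break
    if not suspect_ids:
        return trace
    keep = ~np.isin(trace.point_path_ids.astype(str), [str(s) for s in suspect_ids])
    return LeadTrace(
        trace.lead_name, trace.points[keep],
        tuple(p for p in trace.source_path_ids if p not in suspect_ids),
        trace.point_path_ids[keep],
    )


def resolve_retrace(trace: LeadTrace, x_quantum: float = 1e-6) -> LeadTrace:
    """Collapse repeated x positions to their mean y; sort x strictly increasing."""
    pts = trace.points
    if pts.shape[0] == 0:
        return trace
    xq = np.round(pts[:, 0] / x_quantum) * x_quantum
    ux, inv = np.unique(xq, return_inverse=True)
    sums = np.bincount(inv, weights=pts[:, 1])
    counts = np.bincount(inv)
    my = sums / counts
    # provenance: keep the first contributing path id per unique x
    order = np.argsort(xq, kind="stable")
    first_idx = np.zeros(ux.size, dtype=int)
    seen = np.full(ux.size, -1)
    for j in order:
        k = inv[j]
        if seen[k] < 0:
            seen[k] = j
    first_idx = seen.astype(int)
    new_pts = np.column_stack([ux, my])
    return LeadTrace(trace.lead_name, new_pts, trace.source_path_ids,
                     trace.point_path_ids[first_idx])


def correct_baseline_offset(trace: LeadTrace, layout: LeadLayout) -> LeadTrace:
    """Translate the trace so its isoelectric level sits on the layout baseline.

    Shape is preserved exactly: one constant is added to every y.  When the
    layout baseline was itself estimated from this trace the shift is ~0.
    """
    if trace.points.shape[0] == 0:
        return trace
    est = isoelectric_level(trace.points[:, 1])
    dy = layout.baseline_y[trace.lead_name] - est
    pts = trace.points.copy()
    pts[:, 1] += dy
    return replace(trace, points=pts)


# ---------------------------------------------------------------------------
# full reconstruction

def reconstruct_leads(page: PageGraphics, layout: LeadLayout | None = None,
                      config: LayoutConfig | None = None) -> dict:
    """Run the whole reconstruction: layout, assignment, artifact fixes.

    Returns ``{lead_name: LeadTrace}`` with strictly increasing x per trace.
    """
    cfg = config or LayoutConfig()
    if layout is None:
        layout = detect_layout(page, cfg)
    mapping, _dropped = assign_strokes_to_leads(page, layout)
    out = {}
    for name in layout.lead_order:
        strokes = mapping.get(name, [])
        if not strokes:
            raise LayoutError(f"no strokes assigned to lead {name}", missing=(name,))
        trace = build_trace(name, strokes)
        trace = remove_text_collisions(trace, page.texts)
        trace = resolve_retrace(trace)
        trace = correct_baseline_offset(trace, layout)
        out[name] = trace
    return out
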