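"""Layout detection, stroke-to-lead assignment and artifact resolution."""

import numpy as np
import pytest

from pdfecg.errors import LayoutError
from pdfecg.graphics import TextSpan, classify_strokes, extract_page_graphics
from pdfecg.reconstruct import (
    LeadTrace,
    assign_strokes_to_leads,
    build_trace,
    correct_baseline_offset,
    detect_layout,
    isoelectric_level,
    reconstruct_leads,
    remove_text_collisions,
    resolve_retrace,
)
from pdfecg.synth import (
    BeatModelParams,
    RenderOptions,
    apply_artifacts,
    render_pdf,
    synthesize_ecg,
)


def _classified(data):
    return classify_strokes(extract_page_graphics(data))


# ---------------------------------------------------------------------------
# layout

def test_layout_matches_manifest_with_labels(clean_page):
    data, manifest = clean_page
    layout = detect_layout(_classified(data))
    for lead, b in manifest["layout"]["baseline_y"].items():
        assert layout.baseline_y[lead] == pytest.approx(b, abs=1.0)
        assert layout.time_origin_x[lead] == pytest.approx(
            manifest["layout"]["time_origin_x"][lead], abs=1.0)
        got = layout.strip_boxes[lead]
        want = manifest["layout"]["strip_boxes"][lead]
        assert np.allclose(got, want, atol=1.0)


def test_layout_recovered_without_labels(unlabeled_page):
    data, manifest = unlabeled_page
    layout = detect_layout(_classified(data))
    for lead, b in manifest["layout"]["baseline_y"].items():
        assert layout.baseline_y[lead] == pytest.approx(b, abs=1.0)


def test_missing_lead_raises_layout_error(clean_truth):
    data, _ = render_pdf(clean_truth, options=RenderOptions(drop_leads=("V3",)))
    with pytest.raises(LayoutError) as err:
        detect_layout(_classified(data))
    assert err.value.missing == ("V3",)


# ---------------------------------------------------------------------------
# assignment

def test_stroke_fully_inside_box_assigned(clean_page):
    data, manifest = clean_page
    page = _classified(data)
    layout = detect_layout(page)
    mapping, dropped = assign_strokes_to_leads(page, layout)
    assert not dropped
    for lead, strokes in mapping.items():
        assert [manifest["path_map"][s.path_id] for s in strokes] == [lead]


def test_excursing_path_stays_whole_with_its_lead(artifact_page):
    truth, data, manifest = artifact_page
    page = _classified(data)
    layout = detect_layout(page)
    mapping, _ = assign_strokes_to_leads(page, layout)
    # V2's deep S excurses into V3's strip yet the path stays wholly V2
    v2_ids = {s.path_id for s in mapping["V2"]}
    truth_v2 = {pid for pid, lead in manifest["path_map"].items() if lead == "V2"}
    assert v2_ids == truth_v2
    v3_ids = {s.path_id for s in mapping["V3"]}
    assert v3_ids.isdisjoint(truth_v2)


def test_assignment_conserves_strokes(artifact_page):
    _, data, _ = artifact_page
    page = _classified(data)
    layout = detect_layout(page)
    mapping, dropped = assign_strokes_to_leads(page, layout)
    assert sum(len(v) for v in mapping.values()) + len(dropped) \
        == len(page.waveform_strokes())


# ---------------------------------------------------------------------------
# text collisions

def test_no_collision_returns_trace_unchanged():
    pts = np.column_stack([np.arange(30.0), np.zeros(30)])
    trace = LeadTrace("I", pts, ("p0.0",))
    span = TextSpan("note", (500.0, 500.0, 520.0, 510.0), 8.0)
    assert remove_text_collisions(trace, (span,)) is trace


def test_glyph_stroke_stripped_from_trace():
    truth = synthesize_ecg(BeatModelParams(), seed=31)
    truth = apply_artifacts(truth, label_overlap=("V2",), glyph_strokes=("V2",))
    data, manifest = render_pdf(truth)
    page = _classified(data)
    layout = detect_layout(page)
    mapping, _ = assign_strokes_to_leads(page, layout)
    trace = build_trace("V2", mapping["V2"])
    n_before = trace.points.shape[0]
    cleaned = remove_text_collisions(trace, page.texts)
    assert n_before - cleaned.points.shape[0] == 24   # exactly the glyph's points
    glyph_id = next(pid for pid, lead in manifest["path_map"].items()
                    if lead.startswith("__glyph"))
    assert glyph_id not in cleaned.source_path_ids


# ---------------------------------------------------------------------------
# retrace resolution

def test_retrace_mean_of_duplicates():
    trace = LeadTrace("I", np.array([[0.0, 0.0], [1.0, 2.0], [1.0, 4.0], [2.0, 0.0]]),
                      ("p",))
    out = resolve_retrace(trace)
    np.testing.assert_allclose(out.points, [[0, 0], [1, 3], [2, 0]])


def test_retrace_monotone_identity():
    pts = np.column_stack([np.arange(50.0), np.sin(np.arange(50.0))])
    out = resolve_retrace(LeadTrace("I", pts, ("p",)))
    np.testing.assert_allclose(out.points, pts)


def test_retrace_shuffle_and_duplicate_recovers_original(rng):
    for _ in range(100):
        n = int(rng.integers(5, 60))
        xs = np.sort(rng.choice(np.arange(200.0), size=n, replace=False))
        ys = rng.normal(size=n)
        pts = np.column_stack([xs, ys])
        dup = np.vstack([pts, pts[rng.integers(0, n, size=n // 2)]])
        shuffled = dup[rng.permutation(dup.shape[0])]
        out = resolve_retrace(LeadTrace("I", shuffled, ("p",)))
        np.testing.assert_allclose(out.points, pts, atol=1e-9)


# ---------------------------------------------------------------------------
# baseline correction

def test_dc_shift_recovered_within_one_quantum():
    truth = synthesize_ecg(BeatModelParams(), seed=37)
    truth = apply_artifacts(truth, baseline_shift_mm={"II": 3.0 * 25.4 / 72.0})
    data, _ = render_pdf(truth)
    from pdfecg.pipeline import digitize_page
    rec = digitize_page(data)
    bias = np.mean(rec.leads["II"].samples - truth.record.leads["II"].samples)
    assert abs(bias) * 1000 < 4.88                    # under one ADC quantum


def test_zero_shift_near_identity(clean_page):
    data, _ = clean_page
    page = _classified(data)
    layout = detect_layout(page)
    mapping, _ = assign_strokes_to_leads(page, layout)
    trace = build_trace("I", mapping["I"])
    corrected = correct_baseline_offset(trace, layout)
    shift = corrected.points[0, 1] - trace.points[0, 1]
    assert abs(shift) < 0.5


def test_isoelectric_level_tracks_mode_under_drift():
    # slow sawtooth drift, flat over the first 100 ms where the check applies
    n = 1250
    t = np.arange(n) / 500.0
    drift = np.where(t < 0.4, 0.0, 0.05 * ((t - 0.4) % 0.7))
    y = 100.0 + drift * 28.35
    y[300:320] += 25.0                                # one QRS-like bump
    level = isoelectric_level(y)
    assert level == pytest.approx(100.0, abs=0.3)


def test_reconstruction_idempotent(clean_page):
    data, _ = clean_page
    page = _classified(data)
    layout = detect_layout(page)
    traces = reconstruct_leads(page, layout)
    for name, trace in traces.items():
        again = correct_baseline_offset(resolve_retrace(
            remove_text_collisions(trace, page.texts)), layout)
        np.testing.assert_allclose(again.points, trace.points, atol=1e-9)
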