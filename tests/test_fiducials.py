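"""R-peak detection, wave delineation and the three global measurements."""

import numpy as np
import pytest
from dataclasses import replace

from pdfecg.calibrate import DigitizedLead
from pdfecg.errors import MeasurementError, NoBeatsError
from pdfecg.fiducials import (
    BeatFiducials,
    FiducialSet,
    Wave,
    delineate,
    detect_r_peaks,
    measure_pr_interval,
    measure_qrs_duration,
    measure_record,
    measure_ventricular_rate,
)
from pdfecg.synth import BeatModelParams, synthesize_ecg

FS = 500.0


def _single_beat(center_s=1.2):
    t = np.arange(1250) / FS
    v = 1.0 * np.exp(-0.5 * ((t - center_s) / 0.012) ** 2)
    return DigitizedLead("II", v, FS)


def _fset(lead, r_times_s=None, onsets=None, offsets=None, p_onsets=None, fs=FS):
    """Hand-built FiducialSet; onset/offset/p_onset values are absolute ms."""
    if r_times_s is None:
        # R midway between the stated QRS bounds
        r = [int(round((a + b) / 2 * fs / 1000.0))
             for a, b in zip(onsets, offsets)]
    else:
        r = [int(round(x * fs)) for x in r_times_s]
    beats = []
    for i, _ in enumerate(r):
        waves = {"R": Wave(float(r[i]),
                           None if onsets is None else onsets[i] * fs / 1000.0,
                           None if offsets is None else offsets[i] * fs / 1000.0)}
        if p_onsets is not None:
            waves["P"] = Wave(p_onsets[i] * fs / 1000.0 + 1,
                              p_onsets[i] * fs / 1000.0)
        beats.append(BeatFiducials(waves))
    return FiducialSet(lead, fs, np.array(r), tuple(beats))


# ---------------------------------------------------------------------------
# R-peak detection

def test_single_beat_located_within_two_samples():
    r = detect_r_peaks(_single_beat(1.2))
    assert r.size == 1
    assert abs(r[0] - 600) <= 2


def test_beat_count_at_72_bpm():
    truth = synthesize_ecg(BeatModelParams(rate_bpm=72.0), seed=5)
    r = detect_r_peaks(truth.record.leads["II"])
    assert r.size == 3
    np.testing.assert_allclose(r, truth.fiducials["II"].r_peaks, atol=2)


def test_flat_signal_raises():
    with pytest.raises(NoBeatsError):
        detect_r_peaks(DigitizedLead("II", np.zeros(1250), FS))


def test_refractory_enforced():
    truth = synthesize_ecg(BeatModelParams(rate_bpm=110.0), seed=6)
    r = detect_r_peaks(truth.record.leads["II"])
    assert np.all(np.diff(r) >= 0.2 * FS)


# ---------------------------------------------------------------------------
# delineation

def test_generator_fiducials_recovered_within_4ms():
    truth = synthesize_ecg(BeatModelParams(), seed=7)
    lead = truth.record.leads["II"]
    fset = delineate(lead, detect_r_peaks(lead))
    tset = truth.fiducials["II"]
    matched = 0
    det = {int(round(b.r.peak)): b for b in fset.beats}
    for tr, tb in zip(tset.r_peaks, tset.beats):
        b = det.get(int(tr)) or det.get(int(tr) + 1) or det.get(int(tr) - 1)
        if b is None:
            continue
        # Q offset and S onset fall inside the QRS where waves overlap and no
        # measurement uses them; the exterior landmarks must all agree
        for wname, check_on, check_off in (("P", True, True), ("Q", True, False),
                                           ("R", False, False),
                                           ("S", False, True), ("T", True, True)):
            tw = tb.waves.get(wname)
            w = b.waves.get(wname)
            if tw is None or w is None:
                continue
            assert abs(w.peak - tw.peak) <= 2.0, wname
            if check_on and tw.onset is not None and w.onset is not None:
                assert abs(w.onset - tw.onset) <= 2.0, f"{wname} onset"
            if check_off and tw.offset is not None and w.offset is not None:
                assert abs(w.offset - tw.offset) <= 2.0, f"{wname} offset"
            matched += 1
    assert matched >= 10


def test_absent_p_reported_absent():
    params = BeatModelParams()
    amps = {k: dict(v) for k, v in params.lead_amplitudes.items()}
    for lead in amps:
        amps[lead]["P"] = 0.0
    truth = synthesize_ecg(replace(params, lead_amplitudes=amps), seed=8)
    lead = truth.record.leads["II"]
    fset = delineate(lead, detect_r_peaks(lead))
    assert all("P" not in b.waves for b in fset.beats)


def test_symmetric_qrs_onset_offset_equidistant():
    truth = synthesize_ecg(BeatModelParams(noise_sigma_uV=0.0), seed=9)
    lead = truth.record.leads["II"]
    fset = delineate(lead, detect_r_peaks(lead))
    for b in fset.beats:
        if b.qrs_onset is None or b.qrs_offset is None:
            continue
        left = b.r.peak - b.qrs_onset
        right = b.qrs_offset - b.r.peak
        assert abs(left - right) <= 1.0


# ---------------------------------------------------------------------------
# global measurements (hand-computed arithmetic)

def test_qrs_duration_max_minus_min_across_leads():
    sets = [
        _fset("I", onsets=[98.0], offsets=[190.0]),
        _fset("II", onsets=[102.0], offsets=[194.0]),
        _fset("V1", onsets=[100.0], offsets=[192.0]),
    ]
    assert measure_qrs_duration(sets) == pytest.approx(96.0)


def test_qrs_duration_single_lead():
    sets = [_fset("II", onsets=[100.0], offsets=[180.0])]
    assert measure_qrs_duration(sets) == pytest.approx(80.0)


def test_qrs_duration_requires_some_lead():
    with pytest.raises(MeasurementError):
        measure_qrs_duration([_fset("II", [1.0])])


def test_pr_earliest_p_to_earliest_qrs():
    sets = [_fset("II", onsets=[98.0], offsets=[180.0], p_onsets=[40.0])]
    assert measure_pr_interval(sets) == pytest.approx(58.0)


def test_pr_absent_everywhere_is_none():
    sets = [_fset("II", onsets=[98.0], offsets=[180.0])]
    assert measure_pr_interval(sets) is None


def test_rate_intervals_convention():
    # 5 peaks from 0.1 to 2.1 s: 4 intervals over 2 s -> 120 bpm
    sets = [_fset("II", [0.1, 0.6, 1.1, 1.6, 2.1])]
    assert measure_ventricular_rate(sets) == pytest.approx(120.0)


def test_rate_two_beats_one_second():
    sets = [_fset("II", [0.5, 1.5])]
    assert measure_ventricular_rate(sets) == pytest.approx(60.0)


def test_rate_literal_count_overestimates_by_n_over_n_minus_1():
    sets = [_fset("II", [0.1, 0.6, 1.1, 1.6, 2.1])]
    literal = measure_ventricular_rate(sets, convention="literal_count")
    assert literal == pytest.approx(120.0 * 5 / 4)


def test_rate_needs_two_beats():
    with pytest.raises(MeasurementError):
        measure_ventricular_rate([_fset("II", [1.0])])


# ---------------------------------------------------------------------------
# end-to-end programmed-value recovery and invariants

@pytest.mark.parametrize("pr, qrs, rate", [(160.0, 120.0, 75.0),
                                           (200.0, 90.0, 60.0)])
def test_programmed_intervals_recovered(pr, qrs, rate):
    truth = synthesize_ecg(BeatModelParams(pr_ms=pr, qrs_ms=qrs, rate_bpm=rate),
                           seed=13)
    m = measure_record(truth.record)
    assert m.qrs_ms == pytest.approx(qrs, abs=4.0)
    assert m.pr_ms == pytest.approx(pr, abs=4.0)
    assert m.rate_bpm == pytest.approx(rate, abs=2.0)


def test_twelve_lead_qrs_dominates_single_lead():
    truth = synthesize_ecg(BeatModelParams(), seed=14)
    sets = []
    for name, lead in truth.record.leads.items():
        sets.append(delineate(lead, detect_r_peaks(lead)))
    global_qrs = measure_qrs_duration(sets)
    for s in sets:
        assert global_qrs >= measure_qrs_duration([s]) - 1e-9


def test_rate_times_mean_rr_is_sixty():
    sets = [_fset("II", [0.3, 0.9, 1.5, 2.1])]
    rate = measure_ventricular_rate(sets)
    rr = 0.6
    assert rate * rr == pytest.approx(60.0)
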