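"""Beat detection, P/QRS/T delineation and vendor-style interval measures.

The three global measurements mirror the vendor convention for 12-lead
reports: QRS duration runs from the earliest Q onset in ANY lead to the
latest S offset in ANY lead; the PR interval from the earliest P onset in
any lead to the earliest QRS onset in any lead; ventricular rate comes from
the R-R span of a reference lead.  Onsets and offsets are the points where a
wave leaves/returns to the isoelectric line; here they are located by
half-maximum width extrapolation (onset = peak - 3 sigma with sigma from the
wave's half-width), which is robust at clinical noise levels and coincides
with the conventional +-3 sigma support for Gaussian-shaped waves.  A
slope-threshold fallback covers waves without a clean half-max crossing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy.ndimage import gaussian_filter1d

from pdfecg.calibrate import DigitizedLead, ECGRecord
from pdfecg.errors import MeasurementError, NoBeatsError

__all__ = [
    "RPeakConfig",
    "DelineationConfig",
    "Wave",
    "BeatFiducials",
    "FiducialSet",
    "IntervalMeasurements",
    "detect_r_peaks",
    "delineate",
    "measure_qrs_duration",
    "measure_pr_interval",
    "measure_ventricular_rate",
    "measure_record",
]

_HWHM_TO_SIGMA = 1.0 / np.sqrt(2.0 * np.log(2.0))   # sigma = HWHM * this


@dataclass(frozen=True)
class RPeakConfig:
    refractory_ms: float = 200.0
    band_hz: tuple = (5.0, 30.0)       # QRS energy band for the envelope
    integrate_ms: float = 80.0
    threshold_frac: float = 0.35       # of the max envelope value
    refine_ms: float = 60.0            # search half-window around envelope peak
    edge_guard_ms: float = 100.0       # reject R peaks this close to strip ends
    # (a QRS cannot be fully contained there; edge-partial beats of the
    # neighbouring cycle otherwise masquerade as extra complexes)


@dataclass(frozen=True)
class DelineationConfig:
    qrs_wave_window_ms: float = 80.0    # Q/S search half-window around R
    p_window_ms: tuple = (-300.0, -80.0)   # relative to QRS onset
    t_window_ms: tuple = (80.0, 400.0)     # relative to QRS offset
    p_min_uV: float = 25.0
    qs_min_uV: float = 20.0
    t_min_uV: float = 25.0
    support_sigmas: float = 3.0         # onset/offset at peak -+ k*sigma
    slope_frac: float = 0.055           # fallback: fraction of max |dV/dt|
    beat_match_ms: float = 150.0        # cross-lead beat pairing tolerance
    smooth_sigma_samples: float = 2.0   # pre-smoothing; deconvolved from widths


@dataclass(frozen=True)
class Wave:
    """One wave's landmarks as (possibly fractional) sample positions."""

    peak: float
    onset: float | None = None
    offset: float | None = None
    amplitude_mV: float = 0.0

    def __post_init__(self):
        if self.onset is not None and self.onset > self.peak:
            raise ValueError("wave onset after peak")
        if self.offset is not None and self.offset < self.peak:
            raise ValueError("wave offset before peak")


@dataclass(frozen=True)
class BeatFiducials:
    """Landmarks of one beat; absent waves are simply missing from the dict."""

    waves: dict                      # subset of {"P","Q","R","S","T"} -> Wave

    @property
    def r(self) -> Wave:
        return self.waves["R"]

    @property
    def qrs_onset(self) -> float | None:
        q = self.waves.get("Q")
        if q is not None and q.onset is not None:
            return q.onset
        return self.r.onset

    @property
    def qrs_offset(self) -> float | None:
        s = self.waves.get("S")
        if s is not None and s.offset is not None:
            return s.offset
        return self.r.offset


@dataclass(frozen=True)
class FiducialSet:
    lead_name: str
    fs: float
    r_peaks: np.ndarray              # integer sample indices, strictly increasing
    beats: tuple = ()                # one BeatFiducials per R peak

    def __post_init__(self):
        r = np.asarray(self.r_peaks, dtype=int)
        if r.size and np.any(np.diff(r) <= 0):
            raise ValueError("r_peaks must be strictly increasing")
        object.__setattr__(self, "r_peaks", r)
        if self.beats and len(self.beats) != r.size:
            raise ValueError("one BeatFiducials required per R peak")


@dataclass(frozen=True)
class IntervalMeasurements:
    pr_ms: float | None
    qrs_ms: float
    rate_bpm: float

    def __post_init__(self):
        if self.pr_ms is not None and not 0 < self.pr_ms < 600:
            raise ValueError(f"implausible PR interval {self.pr_ms} ms")
        if not 0 < self.qrs_ms < 400:
            raise ValueError(f"implausible QRS duration {self.qrs_ms} ms")
        if self.rate_bpm <= 0:
            raise ValueError("rate must be positive")


# ---------------------------------------------------------------------------
# R-peak detection (smoothed squared-derivative envelope, adaptive threshold)

def detect_r_peaks(lead: DigitizedLead, config: RPeakConfig | None = None) -> np.ndarray:
    cfg = config or RPeakConfig()
    x = lead.samples
    if lead.fs < 100:
        raise ValueError("sampling rate too low for QRS detection")
    if float(np.ptp(x)) < 1e-6:
        raise NoBeatsError(f"lead {lead.lead_name}: flat signal")

    nyq = lead.fs / 2.0
    hi = min(cfg.band_hz[1], 0.9 * nyq)
    sos = sps.butter(2, [cfg.band_hz[0] / nyq, hi / nyq], btype="band", output="sos")
    f = sps.sosfiltfilt(sos, x - np.median(x))
    env = np.gradient(f) ** 2
    win = max(int(round(cfg.integrate_ms / 1000.0 * lead.fs)), 1)
    env = np.convolve(env, np.ones(win) / win, mode="same")
    if env.max() <= 0:
        raise NoBeatsError(f"lead {lead.lead_name}: no QRS energy")

    distance = max(int(round(cfg.refractory_ms / 1000.0 * lead.fs)), 1)
    peaks, _ = sps.find_peaks(env, height=cfg.threshold_frac * env.max(),
                              distance=distance)
    if peaks.size == 0:
        raise NoBeatsError(f"lead {lead.lead_name}: no beats above threshold")

    # refine to the raw extremum (R apex) near each envelope peak
    base = np.median(x)
    half = max(int(round(cfg.refine_ms / 1000.0 * lead.fs)), 1)
    refined = []
    for p in peaks:
        a, b = max(p - half, 0), min(p + half + 1, x.size)
        refined.append(a + int(np.argmax(np.abs(x[a:b] - base))))
    guard = int(round(cfg.edge_guard_ms / 1000.0 * lead.fs))
    refined = np.unique([r for r in refined if guard <= r < x.size - guard])
    if refined.size == 0:
        raise NoBeatsError(f"lead {lead.lead_name}: only edge-partial beats found")
    # re-enforce refractory after refinement
    keep = [int(refined[0])]
    for r in refined[1:]:
        if r - keep[-1] >= distance:
            keep.append(int(r))
        elif np.abs(x[r] - base) > np.abs(x[keep[-1]] - base):
            keep[-1] = int(r)
    return np.asarray(keep, dtype=int)


# ---------------------------------------------------------------------------
# delineation helpers

def _half_crossing(x: np.ndarray, base: float, peak_idx: int, direction: int,
                   limit: int) -> float | None:
    """Fractional index where |x - base| first falls to half the peak deviation.

    ``direction`` -1 scans left (onset side), +1 right (offset side).
    """
    amp = x[peak_idx] - base
    half = base + amp / 2.0
    prev = peak_idx
    i = peak_idx
    for _ in range(limit):
        i += direction
        if i < 0 or i >= x.size:
            return None
        crossed = (x[i] - half) * np.sign(amp) <= 0
        if crossed:
            # linear interpolation between prev and i
            d = x[prev] - x[i]
            frac = (x[prev] - half) / d if d != 0 else 0.5
            return prev + direction * frac
        prev = i
    return None


def _wave_bounds(x: np.ndarray, base: float, peak: float, fs: float,
                 cfg: DelineationConfig, scan_ms: float = 120.0
                 ) -> tuple[float | None, float | None]:
    """Onset/offset of a wave by half-width extrapolation with slope fallback.

    ``x`` is the pre-smoothed trace and ``peak`` may be fractional; smoothing
    a Gaussian wave widens its variance by the smoothing variance, so that
    inflation is subtracted back out before scaling the half-width to the
    +-3 sigma support.
    """
    peak_idx = int(round(peak))
    limit = int(round(scan_ms / 1000.0 * fs))
    smooth_var = cfg.smooth_sigma_samples ** 2
    out = []
    for direction in (-1, +1):
        c = _half_crossing(x, base, peak_idx, direction, limit)
        if c is not None:
            hwhm = abs(c - peak)
            sigma_meas = hwhm * _HWHM_TO_SIGMA
            sigma = max(np.sqrt(max(sigma_meas ** 2 - smooth_var, 0.0)), 0.5)
            out.append(peak + direction * cfg.support_sigmas * sigma)
        else:
            # slope-threshold fallback around this wave
            a = max(peak_idx - limit, 0)
            b = min(peak_idx + limit + 1, x.size)
            dv = np.gradient(x[a:b])
            thr = cfg.slope_frac * np.max(np.abs(dv)) if dv.size else 0.0
            i = peak_idx - a
            while 0 <= i < dv.size and np.abs(dv[i]) > thr:
                i += direction
            out.append(float(a + np.clip(i, 0, dv.size - 1)))
    onset, offset = out
    if onset is not None:
        onset = float(np.clip(onset, 0, peak))
    if offset is not None:
        offset = float(np.clip(offset, peak, x.size - 1))
    return onset, offset


def _symmetric_wave_bounds(x: np.ndarray, base: float, peak_idx: int, fs: float,
                           cfg: DelineationConfig, scan_ms: float
                           ) -> tuple[float, float | None, float | None]:
    """Centre and +-3 sigma bounds of an isolated symmetric wave (P, T).

    A broad low wave's argmax wanders by several samples under noise, and
    that error is amplified into the extrapolated onset.  The midpoint of
    the two half-maximum crossings is a far steadier centre estimate, and
    their distance gives the width directly.
    """
    limit = int(round(scan_ms / 1000.0 * fs))
    left = _half_crossing(x, base, peak_idx, -1, limit)
    right = _half_crossing(x, base, peak_idx, +1, limit)
    if left is None or right is None:
        onset, offset = _wave_bounds(x, base, float(peak_idx), fs, cfg, scan_ms)
        return float(peak_idx), onset, offset
    centre = (left + right) / 2.0
    sigma_meas = (right - left) / 2.0 * _HWHM_TO_SIGMA
    sigma = max(np.sqrt(max(sigma_meas ** 2 - cfg.smooth_sigma_samples ** 2, 0.0)),
                0.5)
    return centre, centre - cfg.support_sigmas * sigma, centre + cfg.support_sigmas * sigma


def _extremum(x: np.ndarray, base: float, a: int, b: int) -> int | None:
    if b <= a:
        return None
    seg = np.abs(x[a:b] - base)
    return a + int(np.argmax(seg))


def _parabolic_refine(x: np.ndarray, i: int) -> float:
    """Sub-sample vertex of the parabola through (i-1, i, i+1)."""
    if i <= 0 or i >= x.size - 1:
        return float(i)
    denom = x[i - 1] - 2 * x[i] + x[i + 1]
    if denom == 0:
        return float(i)
    delta = 0.5 * (x[i - 1] - x[i + 1]) / denom
    return float(i) + float(np.clip(delta, -0.5, 0.5))


def _directional_peak(x: np.ndarray, base: float, a: int, b: int,
                      min_uV: float, last: bool) -> int | None:
    """Prominent |x - base| local maximum inside [a, b): last (P) or first (T).

    P is the wave nearest the QRS on its left, T the nearest on its right;
    choosing by position instead of by size keeps a neighbouring beat's
    larger wave from hijacking the search window.
    """
    if b <= a:
        return None
    seg = np.abs(x[a:b] - base)
    h = min_uV / 1000.0
    peaks, _ = sps.find_peaks(seg, height=h, prominence=0.6 * h)
    if peaks.size == 0:
        return None
    return a + int(peaks[-1] if last else peaks[0])


def delineate(lead: DigitizedLead, r_peaks, config: DelineationConfig | None = None
              ) -> FiducialSet:
    """Locate P/Q/R/S/T landmarks around each detected R peak.

    Waves whose search window falls outside the strip, or whose amplitude is
    below the per-wave floor, are reported absent rather than fabricated.
    """
    cfg = config or DelineationConfig()
    x = lead.samples
    fs = lead.fs
    # all landmark geometry is read off a lightly smoothed copy; the width
    # inflation this causes is deconvolved inside _wave_bounds
    xs = gaussian_filter1d(x.astype(float), cfg.smooth_sigma_samples)
    # isoelectric mode, not the median: P/T waves skew the plain median by a
    # few uV, which shifts every half-max crossing
    from pdfecg.reconstruct import isoelectric_level
    base = isoelectric_level(xs, mode_window=0.025, bin_width=0.01)
    r_peaks = np.asarray(r_peaks, dtype=int)
    w = int(round(cfg.qrs_wave_window_ms / 1000.0 * fs))

    beats = []
    for r in r_peaks:
        waves: dict[str, Wave] = {}
        r_on, r_off = _wave_bounds(xs, base, r, fs, cfg, scan_ms=60.0)
        waves["R"] = Wave(float(r), r_on, r_off, x[r] - base)
        pol = np.sign(xs[r] - base) or 1.0

        # Q: opposite-polarity extremum immediately before R
        qa, qb = max(r - w, 0), r
        if qb > qa:
            seg = pol * (xs[qa:qb] - base)
            qi = qa + int(np.argmin(seg))
            if abs(xs[qi] - base) * 1000 >= cfg.qs_min_uV and pol * (xs[qi] - base) < 0:
                qf = _parabolic_refine(xs, qi)
                q_on, q_off = _wave_bounds(xs, base, qf, fs, cfg, scan_ms=60.0)
                waves["Q"] = Wave(qf, q_on, q_off, x[qi] - base)
        # S: opposite-polarity extremum immediately after R
        sa, sb = r + 1, min(r + w + 1, x.size)
        if sb > sa:
            seg = pol * (xs[sa:sb] - base)
            si = sa + int(np.argmin(seg))
            if abs(xs[si] - base) * 1000 >= cfg.qs_min_uV and pol * (xs[si] - base) < 0:
                sf = _parabolic_refine(xs, si)
                s_on, s_off = _wave_bounds(xs, base, sf, fs, cfg, scan_ms=60.0)
                waves["S"] = Wave(sf, s_on, s_off, x[si] - base)

        beat = BeatFiducials(waves)
        qrs_on = beat.qrs_onset
        qrs_off = beat.qrs_offset

        # P: the last prominent wave before QRS onset
        if qrs_on is not None:
            pa = int(round(qrs_on + cfg.p_window_ms[0] / 1000.0 * fs))
            pb = int(round(qrs_on + cfg.p_window_ms[1] / 1000.0 * fs))
            pi = _directional_peak(xs, base, max(pa, 0), max(pb, 0),
                                   cfg.p_min_uV, last=True)
            if pi is not None and pa >= 0:
                pf, p_on, p_off = _symmetric_wave_bounds(xs, base, pi, fs, cfg,
                                                         scan_ms=100.0)
                waves["P"] = Wave(pf, p_on, p_off, x[pi] - base)
        # T: the first prominent wave after QRS offset
        if qrs_off is not None:
            ta = int(round(qrs_off + cfg.t_window_ms[0] / 1000.0 * fs))
            tb = int(round(qrs_off + cfg.t_window_ms[1] / 1000.0 * fs))
            ti = _directional_peak(xs, base, min(ta, x.size), min(tb, x.size),
                                   cfg.t_min_uV, last=False)
            if ti is not None and tb <= x.size:
                tf, t_on, t_off = _symmetric_wave_bounds(xs, base, ti, fs, cfg,
                                                         scan_ms=150.0)
                waves["T"] = Wave(tf, t_on, t_off, x[ti] - base)

        beats.append(BeatFiducials(dict(waves)))
    return FiducialSet(lead.lead_name, fs, r_peaks, tuple(beats))


# ---------------------------------------------------------------------------
# cross-lead beat matching and the three global measurements

def _match_beats(sets, tol_ms: float):
    """Group beats across leads by R-peak time; yields lists of (set, beat)."""
    entries = []
    for fs_set in sets:
        for r, beat in zip(fs_set.r_peaks, fs_set.beats):
            entries.append((r / fs_set.fs, fs_set, beat))
    if not entries:
        return []
    entries.sort(key=lambda e: e[0])
    tol = tol_ms / 1000.0
    clusters, current, t_anchor = [], [], None
    for t, fs_set, beat in entries:
        if t_anchor is None or t - t_anchor <= tol:
            current.append((fs_set, beat))
            t_anchor = t if t_anchor is None else t_anchor
        else:
            clusters.append(current)
            current, t_anchor = [(fs_set, beat)], t
    clusters.append(current)
    return clusters


def measure_qrs_duration(sets, config: DelineationConfig | None = None) -> float:
    """Earliest Q onset to latest S offset across leads, averaged over beats (ms)."""
    cfg = config or DelineationConfig()
    sets = list(sets)
    durations = []
    for cluster in _match_beats(sets, cfg.beat_match_ms):
        onsets, offsets = [], []
        for fs_set, beat in cluster:
            if beat.qrs_onset is not None:
                onsets.append(beat.qrs_onset / fs_set.fs)
            if beat.qrs_offset is not None:
                offsets.append(beat.qrs_offset / fs_set.fs)
        if onsets and offsets:
            durations.append((max(offsets) - min(onsets)) * 1000.0)
    if not durations:
        raise MeasurementError("no delineated QRS complex in any lead")
    return float(np.mean(durations))


def measure_pr_interval(sets, config: DelineationConfig | None = None) -> float | None:
    """Earliest P onset to earliest QRS onset across leads, averaged (ms).

    Returns ``None`` when no lead shows a P wave (absence is a value, not an
    error: non-sinus records simply have no PR interval).
    """
    cfg = config or DelineationConfig()
    sets = list(sets)
    intervals = []
    for cluster in _match_beats(sets, cfg.beat_match_ms):
        p_onsets, q_onsets = [], []
        for fs_set, beat in cluster:
            p = beat.waves.get("P")
            if p is not None and p.onset is not None:
                p_onsets.append(p.onset / fs_set.fs)
            if beat.qrs_onset is not None:
                q_onsets.append(beat.qrs_onset / fs_set.fs)
        if p_onsets and q_onsets:
            intervals.append((min(q_onsets) - min(p_onsets)) * 1000.0)
    if not intervals:
        return None
    return float(np.mean(intervals))


def measure_ventricular_rate(sets, reference_lead: str = "II",
                             convention: str = "intervals") -> float:
    """Heart rate in bpm from the reference lead's R peaks.

    ``convention="intervals"`` divides the R-R interval count (n-1) by the
    first-to-last span — the 60/RR identity.  ``"literal_count"`` divides the
    beat count n by the same span, the naive reading of "beats divided by
    time between first and last beat", which overestimates by n/(n-1).
    """
    by_name = {s.lead_name: s for s in sets}
    ref = by_name.get(reference_lead) or next(iter(by_name.values()))
    r = ref.r_peaks
    if r.size < 2:
        raise MeasurementError("need at least two beats to measure rate")
    span_min = (r[-1] - r[0]) / ref.fs / 60.0
    if convention == "intervals":
        n = r.size - 1
    elif convention == "literal_count":
        n = r.size
    else:
        raise ValueError(f"unknown rate convention {convention!r}")
    return float(n / span_min)


def measure_record(record: ECGRecord, r_config: RPeakConfig | None = None,
                   d_config: DelineationConfig | None = None,
                   rate_convention: str = "intervals") -> IntervalMeasurements:
    """Detect, delineate and measure all three intervals for one record."""
    sets = []
    for name, lead in record.leads.items():
        try:
            r = detect_r_peaks(lead, r_config)
        except NoBeatsError:
            continue
        sets.append(delineate(lead, r, d_config))
    if not sets:
        raise MeasurementError("no lead with detectable beats")
    qrs = measure_qrs_duration(sets, d_config)
    pr = measure_pr_interval(sets, d_config)
    rate = measure_ventricular_rate(sets, convention=rate_convention)
    return IntervalMeasurements(pr, qrs, rate)
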