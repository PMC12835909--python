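"""Physical calibration: page coordinates -> seconds and millivolts.

The vendor chart convention is 25 mm/s and 10 mm/mV with one plotted vertex
every 0.05 mm, i.e. a 500 Hz sample stream, and amplitudes quantized in
4.88 uV steps.  Everything that converts page units to physical units lives
here; upstream modules never see seconds or millivolts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import signal as sps

from pdfecg.errors import FilterSpecError, ShortStripError

__all__ = [
    "LEAD_ORDER",
    "CalibrationParams",
    "DigitizedLead",
    "ECGRecord",
    "FilterSpec",
    "page_to_physical",
    "physical_to_page",
    "resample_uniform",
    "quantize_amplitude",
    "dequantize_amplitude",
    "filter_signal",
    "record_to_csv",
    "record_from_csv",
]

#: Printed lead order on the vendor page (two columns of six strips).
LEAD_ORDER = ("I", "II", "III", "aVF", "aVR", "aVL",
              "V1", "V2", "V3", "V4", "V5", "V6")


@dataclass(frozen=True)
class CalibrationParams:
    """Chart geometry and ADC scale of the source device."""

    mm_per_second: float = 25.0
    mm_per_mV: float = 10.0
    sample_spacing_mm: float = 0.05
    sampling_rate_hz: float = 500.0
    amplitude_quantum_uV: float = 4.88
    page_units_per_mm: float = 72.0 / 25.4
    strip_seconds: float = 2.5

    def __post_init__(self):
        vals = (self.mm_per_second, self.mm_per_mV, self.sample_spacing_mm,
                self.sampling_rate_hz, self.amplitude_quantum_uV,
                self.page_units_per_mm, self.strip_seconds)
        if any(v <= 0 for v in vals):
            raise ValueError("all calibration parameters must be positive")
        # chart consistency: spacing x rate must reproduce the paper speed
        if not np.isclose(self.sample_spacing_mm * self.sampling_rate_hz,
                          self.mm_per_second, rtol=1e-9):
            raise ValueError(
                "inconsistent calibration: sample_spacing_mm * sampling_rate_hz "
                f"= {self.sample_spacing_mm * self.sampling_rate_hz} "
                f"!= mm_per_second = {self.mm_per_second}"
            )

    @property
    def page_units_per_second(self) -> float:
        return self.page_units_per_mm * self.mm_per_second

    @property
    def page_units_per_mV(self) -> float:
        return self.page_units_per_mm * self.mm_per_mV

    @property
    def n_samples(self) -> int:
        return int(round(self.strip_seconds * self.sampling_rate_hz))


@dataclass(frozen=True)
class DigitizedLead:
    """One calibrated lead: uniform samples in millivolts."""

    lead_name: str
    samples: np.ndarray
    fs: float = 500.0
    t0: float = 0.0

    def __post_init__(self):
        arr = np.asarray(self.samples, dtype=float)
        if arr.ndim != 1 or arr.size == 0:
            raise ValueError("samples must be a non-empty 1-D array")
        if not np.all(np.isfinite(arr)):
            raise ValueError("samples contain non-finite values")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        object.__setattr__(self, "samples", arr)

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.samples.size) / self.fs


@dataclass
class ECGRecord:
    """Twelve calibrated leads plus identity and optional vendor measurements."""

    leads: dict
    patient_id: str = ""
    record_id: str = ""
    acquired_at: str | None = None
    vendor_measurements: dict | None = None   # {"pr_ms", "qrs_ms", "rate_bpm"}

    def __post_init__(self):
        if len(self.leads) != 12:
            raise ValueError(f"record needs 12 leads, got {len(self.leads)}")
        lengths = {ld.samples.size for ld in self.leads.values()}
        rates = {ld.fs for ld in self.leads.values()}
        if len(lengths) != 1 or len(rates) != 1:
            raise ValueError("all leads must share sampling rate and length")

    @property
    def fs(self) -> float:
        return next(iter(self.leads.values())).fs

    @property
    def n_samples(self) -> int:
        return next(iter(self.leads.values())).samples.size

    def matrix(self, order=LEAD_ORDER) -> np.ndarray:
        """(12, n) array in the given lead order."""
        return np.vstack([self.leads[name].samples for name in order])


# ---------------------------------------------------------------------------
# conversions

def page_to_physical(x, y, baseline_y: float, time_origin_x: float,
                     calib: CalibrationParams) -> tuple[np.ndarray, np.ndarray]:
    """Map page coordinates to (t seconds, v millivolts) for one strip."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    t = (x - time_origin_x) / calib.page_units_per_second
    v = (y - baseline_y) / calib.page_units_per_mV
    return t, v


def physical_to_page(t, v, baseline_y: float, time_origin_x: float,
                     calib: CalibrationParams) -> tuple[np.ndarray, np.ndarray]:
    """Exact inverse of :func:`page_to_physical` (renderer side)."""
    t = np.asarray(t, dtype=float)
    v = np.asarray(v, dtype=float)
    x = time_origin_x + t * calib.page_units_per_second
    y = baseline_y + v * calib.page_units_per_mV
    return x, y


def resample_uniform(t, v, calib: CalibrationParams, lead_name: str = "",
                     t0: float = 0.0) -> DigitizedLead:
    """Linear interpolation of an irregular (t, v) trace onto the 500 Hz grid.

    The grid is ``t0 + k/fs`` for ``k = 0 .. N-1`` with N = strip_seconds*fs.
    Ends are held (no extrapolation); a trace covering less than 80% of the
    strip raises :class:`ShortStripError`.
    """
    t = np.asarray(t, dtype=float)
    v = np.asarray(v, dtype=float)
    if t.size < 2:
        raise ShortStripError("trace has fewer than two points")
    if np.any(np.diff(t) <= 0):
        raise ValueError("time vector must be strictly increasing")
    span = t[-1] - t[0]
    if span < 0.8 * calib.strip_seconds:
        raise ShortStripError(
            f"trace spans {span:.3f}s, expected >= {0.8 * calib.strip_seconds:.3f}s"
        )
    grid = t0 + np.arange(calib.n_samples) / calib.sampling_rate_hz
    out = np.interp(grid, t, v)   # np.interp holds edge values
    return DigitizedLead(lead_name, out, calib.sampling_rate_hz, t0)


def quantize_amplitude(v, calib: CalibrationParams) -> np.ndarray:
    """Millivolts -> integer ADC quanta (ties to even, the IEEE default)."""
    q = np.rint(np.asarray(v, dtype=float) * 1000.0 / calib.amplitude_quantum_uV)
    return q.astype(np.int64) if np.ndim(q) else int(q)


def dequantize_amplitude(q, calib: CalibrationParams) -> np.ndarray:
    return np.asarray(q, dtype=float) * calib.amplitude_quantum_uV / 1000.0


# ---------------------------------------------------------------------------
# filtering

@dataclass(frozen=True)
class FilterSpec:
    """Zero-phase filtering stack: high-pass, low-pass and optional mains notch.

    Defaults follow clinical convention (0.5 Hz baseline-wander high-pass,
    150 Hz diagnostic low-pass); the notch is off unless mains interference
    is expected.  Applied forward-backward so fiducial timing is not skewed.
    """

    hp_cutoff_hz: float | None = 0.5
    lp_cutoff_hz: float | None = 150.0
    notch_hz: float | None = None
    notch_q: float = 30.0
    order: int = 4


def filter_signal(lead: DigitizedLead, spec: FilterSpec | None = None) -> DigitizedLead:
    spec = spec or FilterSpec()
    nyq = lead.fs / 2.0
    x = lead.samples.astype(float)
    for cutoff in (spec.hp_cutoff_hz, spec.lp_cutoff_hz, spec.notch_hz):
        if cutoff is not None and cutoff >= nyq:
            raise FilterSpecError(f"cutoff {cutoff} Hz >= Nyquist {nyq} Hz")
    if spec.hp_cutoff_hz:
        sos = sps.butter(spec.order, spec.hp_cutoff_hz / nyq, btype="high", output="sos")
        x = sps.sosfiltfilt(sos, x)
    if spec.lp_cutoff_hz:
        sos = sps.butter(spec.order, spec.lp_cutoff_hz / nyq, btype="low", output="sos")
        x = sps.sosfiltfilt(sos, x)
    if spec.notch_hz:
        b, a = sps.iirnotch(spec.notch_hz, spec.notch_q, fs=lead.fs)
        x = sps.filtfilt(b, a, x)
    return DigitizedLead(lead.lead_name, x, lead.fs, lead.t0)


# ---------------------------------------------------------------------------
# persistence (CSV signal table + JSON sidecar)

def record_to_csv(record: ECGRecord, csv_path, sidecar_path=None,
                  calib: CalibrationParams | None = None) -> None:
    """Write the record as a (t, I..V6) table plus a JSON provenance sidecar."""
    t = next(iter(record.leads.values())).times
    df = pd.DataFrame({"t_s": t})
    for name in LEAD_ORDER:
        df[name] = record.leads[name].samples
    df.to_csv(csv_path, index=False, float_format="%.6f")
    if sidecar_path is not None:
        meta = {
            "patient_id": record.patient_id,
            "record_id": record.record_id,
            "acquired_at": record.acquired_at,
            "fs_hz": record.fs,
            "n_samples": record.n_samples,
            "vendor_measurements": record.vendor_measurements,
            "calibration": asdict(calib) if calib else None,
            "lead_order": list(LEAD_ORDER),
        }
        with open(sidecar_path, "w") as fh:
            json.dump(meta, fh, indent=1)


def record_from_csv(csv_path, sidecar_path=None) -> ECGRecord:
    df = pd.read_csv(csv_path)
    meta = {}
    if sidecar_path is not None:
        with open(sidecar_path) as fh:
            meta = json.load(fh)
    fs = float(meta.get("fs_hz", 500.0))
    t0 = float(df["t_s"].iloc[0])
    leads = {name: DigitizedLead(name, df[name].to_numpy(), fs, t0)
             for name in LEAD_ORDER}
    return ECGRecord(
        leads,
        patient_id=meta.get("patient_id", ""),
        record_id=meta.get("record_id", ""),
        acquired_at=meta.get("acquired_at"),
        vendor_measurements=meta.get("vendor_measurements"),
    )
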