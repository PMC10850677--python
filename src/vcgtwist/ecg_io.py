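"""Reading, validation, resampling, filtering and lead reduction of multilead ECGs.

The in-memory container is :class:`EcgRecord`: a ``[n_leads x n_samples]``
matrix in microvolts with an explicit sampling frequency.  All downstream
analysis assumes microvolt amplitudes, which is why ingestion either receives
microvolt data or an explicit gain to convert with.

Supported on-disk format is a simple CSV dialect:

* header row with lead names,
* optionally a first column ``time_ms`` (used to infer the sampling rate),
* one column per lead, amplitudes in microvolts.

Lead reduction produces either the eight algebraically independent leads of a
standard 12-lead ECG (I, II, V1-V6) or three bipolar "chest belt" leads formed
as pairwise differences of precordial electrodes (V2-V1, V5-V2, V6-V5); the
shared Wilson-terminal reference cancels in the subtraction.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.interpolate import CubicSpline

from .errors import (
    FilterConfigError,
    FormatError,
    LeadSetError,
    ResampleError,
    SignalQualityError,
)

#: Canonical order of the algebraically independent leads of a 12-lead ECG.
INDEPENDENT_LEADS = ("I", "II", "V1", "V2", "V3", "V4", "V5", "V6")

#: Labels of the derived chest-belt leads.
BELT_LEADS = ("V2-V1", "V5-V2", "V6-V5")

#: Redundant limb leads that are algebraic combinations of I and II.
REDUNDANT_LEADS = ("III", "aVR", "aVL", "aVF")

#: Tolerance (µV) for the Einthoven/Goldberger consistency check on
#: redundant limb leads, used to detect mislabelled files.
REDUNDANT_LEAD_TOL_UV = 5.0

TIME_COLUMN = "time_ms"


@dataclass(frozen=True)
class EcgRecord:
    """A multilead ECG signal matrix in microvolts.

    Parameters
    ----------
    lead_labels
        Ordered, unique lead names, one per signal row.
    signal
        ``[n_leads x n_samples]`` float array, microvolts.
    fs
        Sampling frequency in Hz.
    t0
        Start-time offset in milliseconds (default 0).
    """

    lead_labels: tuple[str, ...]
    signal: np.ndarray
    fs: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        sig = np.asarray(self.signal, dtype=float)
        if sig.ndim != 2:
            raise SignalQualityError("signal must be a 2-D [leads x samples] matrix")
        object.__setattr__(self, "signal", sig)
        object.__setattr__(self, "lead_labels", tuple(self.lead_labels))
        if len(self.lead_labels) != sig.shape[0]:
            raise LeadSetError(
                f"{len(self.lead_labels)} labels for {sig.shape[0]} signal rows"
            )
        if len(set(self.lead_labels)) != len(self.lead_labels):
            raise LeadSetError("lead labels must be unique")
        if sig.shape[0] < 3:
            raise LeadSetError("at least 3 leads required")
        if not self.fs > 0:
            raise SignalQualityError(f"sampling frequency must be positive, got {self.fs}")
        if not np.isfinite(sig).all():
            raise SignalQualityError("signal contains non-finite samples")

    @property
    def n_leads(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def lead(self, label: str) -> np.ndarray:
        """Return the signal row for one lead."""
        try:
            return self.signal[self.lead_labels.index(label)]
        except ValueError:
            raise LeadSetError(f"lead {label!r} not present") from None

    def has_leads(self, labels) -> bool:
        return set(labels).issubset(self.lead_labels)


@dataclass(frozen=True)
class LeadSetTag:
    """Tag identifying which reduced lead set a result was computed on."""

    tag: str  # "FULL8" or "BELT3"

    def __post_init__(self) -> None:
        if self.tag not in ("FULL8", "BELT3"):
            raise LeadSetError(f"unknown lead-set tag {self.tag!r}")

    @property
    def leads(self) -> tuple[str, ...]:
        return INDEPENDENT_LEADS if self.tag == "FULL8" else BELT_LEADS


FULL8 = LeadSetTag("FULL8")
BELT3 = LeadSetTag("BELT3")


@dataclass(frozen=True)
class FilterSettings:
    """Zero-phase filter configuration for a 1 kHz record.

    Defaults follow standard resting-ECG practice: a gentle 0.5 Hz high-pass
    removes DC and baseline drift without distorting the ST segment, a 150 Hz
    low-pass suppresses muscle noise above the diagnostic band, and an
    optional mains notch removes 50/60 Hz interference.
    """

    highpass_hz: float | None = 0.5
    lowpass_hz: float | None = 150.0
    notch_hz: float | None = None
    notch_q: float = 30.0


# ---------------------------------------------------------------------------
# Reading and writing
# ---------------------------------------------------------------------------


def read_ecg(
    path,
    format: str = "csv",
    fs: float | None = None,
    units: str = "uV",
    gain_to_uv: float | None = None,
) -> EcgRecord:
    """Read an ECG recording from disk.

    Parameters
    ----------
    path
        File to read.
    format
        Only ``"csv"`` is supported (the dialect documented in the module
        docstring).
    fs
        Sampling frequency in Hz; required when the file has no ``time_ms``
        column.
    units
        Unit of the stored amplitudes.  ``"uV"`` is accepted as-is; anything
        else is rejected unless ``gain_to_uv`` is supplied.
    gain_to_uv
        Multiplicative factor converting stored amplitudes to microvolts.
    """
    if format != "csv":
        raise FormatError(
            f"unsupported format {format!r}: this build reads the documented "
            "CSV dialect only"
        )
    if units != "uV" and gain_to_uv is None:
        raise FormatError(
            f"amplitude unit {units!r} requires an explicit gain_to_uv factor"
        )
    df = pd.read_csv(path, float_precision="round_trip")
    if df.shape[1] < 1 or df.shape[0] < 1:
        raise SignalQualityError(f"{path}: empty file")
    cols = list(df.columns)
    if cols[0] == TIME_COLUMN:
        t = df[TIME_COLUMN].to_numpy(dtype=float)
        if len(t) < 2:
            raise SignalQualityError(f"{path}: need at least 2 samples")
        dt = np.diff(t)
        if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
            raise SignalQualityError(f"{path}: non-uniform time column")
        fs_file = 1000.0 / dt[0]
        if fs is not None and not np.isclose(fs, fs_file, rtol=1e-6):
            raise SignalQualityError(
                f"{path}: declared fs={fs} conflicts with time column ({fs_file:.6g})"
            )
        fs = fs_file
        t0 = float(t[0])
        lead_cols = cols[1:]
    else:
        if fs is None:
            raise FormatError(f"{path}: no time_ms column; fs must be supplied")
        t0 = 0.0
        lead_cols = cols
    sig = df[lead_cols].to_numpy(dtype=float).T
    if not np.isfinite(sig).all():
        raise SignalQualityError(f"{path}: non-finite samples")
    if gain_to_uv is not None:
        sig = sig * float(gain_to_uv)
    return EcgRecord(tuple(lead_cols), sig, float(fs), t0)


def write_ecg(rec: EcgRecord, path, include_time: bool = True) -> None:
    """Write a record in the CSV dialect; float formatting is lossless."""
    data: dict[str, np.ndarray] = {}
    if include_time:
        data[TIME_COLUMN] = rec.t0 + np.arange(rec.n_samples) * (1000.0 / rec.fs)
    for label, row in zip(rec.lead_labels, rec.signal):
        data[label] = row
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# Resampling and filtering
# ---------------------------------------------------------------------------


def resample_cubic_spline(rec: EcgRecord, target_fs: float = 1000.0) -> EcgRecord:
    """Resample a record to ``target_fs`` with cubic-spline interpolation.

    A record already at the target rate is returned unchanged.  The duration
    is preserved to within one input sample.
    """
    if rec.fs < 100.0:
        raise ResampleError(f"sampling rate {rec.fs} Hz below the 100 Hz floor")
    if np.isclose(rec.fs, target_fs):
        return rec
    t_in = np.arange(rec.n_samples) / rec.fs
    n_out = int(np.floor(t_in[-1] * target_fs)) + 1
    t_out = np.arange(n_out) / target_fs
    spline = CubicSpline(t_in, rec.signal, axis=1)
    return replace(rec, signal=spline(t_out), fs=float(target_fs))


def filter_record(rec: EcgRecord, cfg: FilterSettings = FilterSettings()) -> EcgRecord:
    """Apply the configured zero-phase filters.

    All stages use forward-backward filtering, so fiducial points are not
    shifted.  Raises :class:`FilterConfigError` for cutoffs that are not
    ordered or exceed the Nyquist frequency.
    """
    nyq = rec.fs / 2.0
    hp, lp = cfg.highpass_hz, cfg.lowpass_hz
    if hp is not None and not 0 < hp < nyq:
        raise FilterConfigError(f"high-pass cutoff {hp} Hz outside (0, {nyq})")
    if lp is not None and not 0 < lp < nyq:
        raise FilterConfigError(f"low-pass cutoff {lp} Hz outside (0, {nyq})")
    if hp is not None and lp is not None and hp >= lp:
        raise FilterConfigError(f"high-pass {hp} Hz >= low-pass {lp} Hz")
    if cfg.notch_hz is not None and not 0 < cfg.notch_hz < nyq:
        raise FilterConfigError(f"notch {cfg.notch_hz} Hz outside (0, {nyq})")

    sig = rec.signal
    if hp is not None:
        sos = sps.butter(3, hp, btype="highpass", fs=rec.fs, output="sos")
        sig = sps.sosfiltfilt(sos, sig, axis=1)
    if lp is not None:
        sos = sps.butter(4, lp, btype="lowpass", fs=rec.fs, output="sos")
        sig = sps.sosfiltfilt(sos, sig, axis=1)
    if cfg.notch_hz is not None:
        b, a = sps.iirnotch(cfg.notch_hz, cfg.notch_q, fs=rec.fs)
        sig = sps.filtfilt(b, a, sig, axis=1)
    return replace(rec, signal=sig)


# ---------------------------------------------------------------------------
# Lead reduction
# ---------------------------------------------------------------------------


def _check_redundant_leads(rec: EcgRecord) -> None:
    """Verify redundant limb leads against the Einthoven/Goldberger identities.

    Detects mislabelled files; redundant leads are then dropped.
    """
    lead_i = rec.lead("I")
    lead_ii = rec.lead("II")
    expected = {
        "III": lead_ii - lead_i,
        "aVR": -(lead_i + lead_ii) / 2.0,
        "aVL": lead_i - lead_ii / 2.0,
        "aVF": lead_ii - lead_i / 2.0,
    }
    for label, ref in expected.items():
        if label in rec.lead_labels:
            dev = np.max(np.abs(rec.lead(label) - ref))
            if dev > REDUNDANT_LEAD_TOL_UV:
                raise LeadSetError(
                    f"redundant lead {label} deviates {dev:.1f} µV from its "
                    f"algebraic reconstruction (> {REDUNDANT_LEAD_TOL_UV} µV): "
                    "possible lead mislabelling"
                )


def to_independent_leads(rec: EcgRecord) -> EcgRecord:
    """Reduce to the 8 algebraically independent leads I, II, V1-V6.

    Redundant limb leads, when present, are first checked for algebraic
    consistency and then dropped.  A record already holding exactly the
    canonical 8 leads in order is returned unchanged.
    """
    missing = [l for l in INDEPENDENT_LEADS if l not in rec.lead_labels]
    if missing:
        raise LeadSetError(f"missing independent leads: {missing}")
    if rec.lead_labels == INDEPENDENT_LEADS:
        return rec
    _check_redundant_leads(rec)
    sig = np.vstack([rec.lead(l) for l in INDEPENDENT_LEADS])
    return replace(rec, lead_labels=INDEPENDENT_LEADS, signal=sig)


def to_belt_leads(rec: EcgRecord) -> EcgRecord:
    """Derive the three chest-belt leads V2-V1, V5-V2, V6-V5.

    The belt models four precordial electrodes read as bipolar pairs; the
    common Wilson-terminal reference cancels in each difference.  The three
    leads telescope: (V2-V1) + (V5-V2) + (V6-V5) = V6-V1 exactly.
    """
    needed = ("V1", "V2", "V5", "V6")
    missing = [l for l in needed if l not in rec.lead_labels]
    if missing:
        raise LeadSetError(f"missing precordial leads for belt derivation: {missing}")
    v1, v2, v5, v6 = (rec.lead(l) for l in needed)
    sig = np.vstack([v2 - v1, v5 - v2, v6 - v5])
    return replace(rec, lead_labels=BELT_LEADS, signal=sig)
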