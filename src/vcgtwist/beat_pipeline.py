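"""QRS detection, median-beat construction, delineation and interval measures.

The representative beat of a recording is the per-lead, per-sample median of
R-aligned beats — robust to transient artefacts that corrupt single beats.
Delineation (QRS onset/offset, T offset) operates on the root-sum-of-squares
vector magnitude of all leads, the standard device-independent view of a
multilead beat.  Scalar indices follow the usual definitions: heart rate from
the mean RR of the whole recording, QT from QRS onset to T offset, Fridericia
rate correction QTc = QT / (RR_s)^(1/3), and TpTe from the T apex of the
vector magnitude to the T offset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy.ndimage import uniform_filter1d

from .ecg_io import EcgRecord
from .errors import DelineationError, InsufficientBeatsError, SignalQualityError

MIN_BEATS = 3
REFRACTORY_MS = 200.0

#: Width of the moving-RMS smoothing that defines the R apex.  A multilead
#: vector magnitude can be multi-humped within the QRS, and narrow windows
#: leave a flat apex plateau that filter ripple can tilt; a window close to
#: the QRS duration gives a single well-curved apex.  The synthetic generator
#: defines its ground-truth R times with the same functional.
R_APEX_SMOOTH_MS = 60


def vector_magnitude(signal: np.ndarray) -> np.ndarray:
    """Root-sum-of-squares across leads, one value per sample."""
    return np.sqrt(np.sum(np.square(signal), axis=0))


def smoothed_magnitude(signal: np.ndarray, win_ms: int = R_APEX_SMOOTH_MS) -> np.ndarray:
    """Moving-RMS of the vector magnitude (robust to within-QRS dips)."""
    return _smooth_rms(vector_magnitude(signal), win_ms)


def _smooth_rms(x: np.ndarray, win_ms: int = 15) -> np.ndarray:
    # moving RMS: robust to the isolated zeros a multiphasic magnitude can have
    sm = uniform_filter1d(np.square(x), size=win_ms, mode="nearest")
    return np.sqrt(np.maximum(sm, 0.0))


@dataclass(frozen=True)
class BeatAnnotations:
    """Detected R-peak times (ms from record start) and RR intervals."""

    r_times: tuple[float, ...]

    def __post_init__(self) -> None:
        t = np.asarray(self.r_times, dtype=float)
        if np.any(np.diff(t) <= 0):
            raise DelineationError("R times must be strictly increasing")
        object.__setattr__(self, "r_times", tuple(t))

    @property
    def rr_intervals(self) -> np.ndarray:
        return np.diff(np.asarray(self.r_times))

    @property
    def mean_rr_ms(self) -> float:
        return float(np.mean(self.rr_intervals))


@dataclass(frozen=True)
class MedianBeat:
    """Per-lead median beat at 1 kHz, aligned on the R peak."""

    beat: np.ndarray  # [n_leads x n_samples], µV
    r_index: int
    n_beats_used: int
    leads: tuple[str, ...]
    mean_rr_ms: float
    fs: float = 1000.0

    def __post_init__(self) -> None:
        if self.n_beats_used < MIN_BEATS:
            raise InsufficientBeatsError(
                f"median beat built from {self.n_beats_used} beats (< {MIN_BEATS})"
            )

    @property
    def n_samples(self) -> int:
        return self.beat.shape[1]


@dataclass(frozen=True)
class Delineation:
    """Fiducial points in ms relative to the median-beat start."""

    qrs_on: float
    qrs_off: float
    t_off: float
    source: str = "automatic"  # or "manual"

    def __post_init__(self) -> None:
        if not self.qrs_on < self.qrs_off < self.t_off:
            raise DelineationError(
                f"fiducials must satisfy qrs_on < qrs_off < t_off, got "
                f"{self.qrs_on}, {self.qrs_off}, {self.t_off}"
            )


@dataclass(frozen=True)
class EcgMeasurements:
    """Scalar interval indices of one recording (ms, bpm)."""

    heart_rate: float
    mean_rr: float
    qrs_duration: float
    qt: float
    qtc_fridericia: float
    t_peak: float
    tpte: float
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for name in ("heart_rate", "mean_rr", "qrs_duration", "qt", "qtc_fridericia", "tpte"):
            if getattr(self, name) <= 0:
                raise DelineationError(f"{name} must be positive")
        if self.qt <= self.qrs_duration:
            raise DelineationError("QT must exceed QRS duration")
        if self.tpte >= self.qt:
            raise DelineationError("TpTe must be shorter than QT")

    def to_dict(self) -> dict:
        d = {
            "heart_rate_bpm": self.heart_rate,
            "mean_rr_ms": self.mean_rr,
            "qrs_duration_ms": self.qrs_duration,
            "qt_ms": self.qt,
            "qtc_fridericia_ms": self.qtc_fridericia,
            "t_peak_ms": self.t_peak,
            "tpte_ms": self.tpte,
        }
        if self.flags:
            d["flags"] = ";".join(self.flags)
        return d


# ---------------------------------------------------------------------------
# QRS detection
# ---------------------------------------------------------------------------


def detect_qrs(
    rec: EcgRecord,
    refractory_ms: float = REFRACTORY_MS,
    rel_threshold: float = 0.3,
) -> BeatAnnotations:
    """Detect R peaks on the vector magnitude with an integrated-energy envelope.

    The squared magnitude is integrated over an 80 ms window; envelope peaks
    above ``rel_threshold`` of the largest envelope value, separated by the
    refractory period, mark beats.  Each detection is refined to the apex of
    the smoothed magnitude within +/-60 ms and then template-aligned against
    the ensemble-average beat shape.
    """
    if rec.duration_s < 3.0:
        raise SignalQualityError("need at least 3 s of signal for QRS detection")
    ms_per_sample = 1000.0 / rec.fs
    mag = vector_magnitude(rec.signal - np.median(rec.signal, axis=1, keepdims=True))
    if np.ptp(mag) < 10.0:
        raise SignalQualityError("flat signal: vector magnitude spans < 10 µV")

    win = max(int(80 / ms_per_sample), 1)
    envelope = uniform_filter1d(np.square(mag), size=win, mode="nearest")
    height = rel_threshold * float(np.max(envelope))
    distance = max(int(refractory_ms / ms_per_sample), 1)
    peaks, _ = sps.find_peaks(envelope, height=height, distance=distance)
    if len(peaks) < MIN_BEATS:
        raise InsufficientBeatsError(f"only {len(peaks)} beats detected")

    mag_s = _smooth_rms(mag, max(int(R_APEX_SMOOTH_MS / ms_per_sample), 1))
    half = int(60 / ms_per_sample)
    refined = []
    for p in peaks:
        lo, hi = max(p - half, 0), min(p + half + 1, len(mag))
        refined.append(lo + int(np.argmax(mag_s[lo:hi])))
    refined = _template_align(mag_s, refined, ms_per_sample)
    # de-duplicate refinements that collapsed onto the same R peak
    r_times = [refined[0] * ms_per_sample]
    for i in refined[1:]:
        t = i * ms_per_sample
        if t - r_times[-1] >= refractory_ms:
            r_times.append(t)
    if len(r_times) < MIN_BEATS:
        raise InsufficientBeatsError(f"only {len(r_times)} beats after refinement")
    return BeatAnnotations(tuple(r_times))


def _template_align(mag_s, peaks, ms_per_sample, span_ms=120, max_shift_ms=20):
    """Tighten beat alignment by correlating each beat with the ensemble mean.

    The smoothed-magnitude apex can sit on a flat plateau, where noise moves
    the argmax by several milliseconds; maximising the inner product with the
    average beat shape removes that beat-to-beat jitter.
    """
    span = int(span_ms / ms_per_sample)
    max_shift = int(max_shift_ms / ms_per_sample)
    n = len(mag_s)
    usable = [p for p in peaks if p - span - max_shift >= 0 and p + span + max_shift < n]
    if len(usable) < len(peaks) or len(usable) < 2:
        return peaks
    template = np.mean([mag_s[p - span : p + span + 1] for p in usable], axis=0)
    aligned = []
    for p in peaks:
        best, best_score = p, -np.inf
        for shift in range(-max_shift, max_shift + 1):
            q = p + shift
            if q - span < 0 or q + span + 1 > n:
                continue
            score = float(template @ mag_s[q - span : q + span + 1])
            if score > best_score:
                best_score, best = score, q
        aligned.append(best)
    return aligned


# ---------------------------------------------------------------------------
# Median beat
# ---------------------------------------------------------------------------


def build_median_beat(
    rec: EcgRecord,
    ann: BeatAnnotations,
    pre_ms: int = 300,
    post_ms: int = 600,
    corr_threshold: float = 0.9,
) -> MedianBeat:
    """Median beatform across R-aligned, morphology-screened beats.

    Beats whose correlation with the ensemble average falls below
    ``corr_threshold`` are excluded.  The post-R extent shrinks to 85% of the
    mean RR when the heart rate is high, so neighbouring beats never leak into
    the representative beat.
    """
    if rec.fs != 1000.0:
        raise SignalQualityError("median beat requires a 1 kHz record")
    mean_rr = ann.mean_rr_ms
    post = int(min(post_ms, 0.85 * mean_rr))
    pre = int(min(pre_ms, 0.4 * mean_rr))

    windows = []
    for t in ann.r_times:
        i = int(round(t))
        if i - pre >= 0 and i + post <= rec.n_samples:
            windows.append(rec.signal[:, i - pre : i + post])
    if len(windows) < MIN_BEATS:
        raise InsufficientBeatsError(
            f"only {len(windows)} complete beat windows in the record"
        )
    stack = np.stack(windows)  # [n_beats, n_leads, n_window]
    flat = stack.reshape(stack.shape[0], -1)
    ensemble = flat.mean(axis=0)
    ens_c = ensemble - ensemble.mean()
    denom_e = np.linalg.norm(ens_c)
    keep = []
    for k in range(flat.shape[0]):
        b = flat[k] - flat[k].mean()
        denom = np.linalg.norm(b) * denom_e
        corr = float(b @ ens_c / denom) if denom > 0 else 0.0
        if corr >= corr_threshold:
            keep.append(k)
    if len(keep) < MIN_BEATS:
        raise InsufficientBeatsError(
            f"only {len(keep)} beats pass morphology screening"
        )
    beat = np.median(stack[keep], axis=0)
    return MedianBeat(
        beat=beat,
        r_index=pre,
        n_beats_used=len(keep),
        leads=rec.lead_labels,
        mean_rr_ms=mean_rr,
    )


# ---------------------------------------------------------------------------
# Delineation
# ---------------------------------------------------------------------------


def _baseline_corrected(mb: MedianBeat) -> np.ndarray:
    """Median beat with each lead's terminal-50 ms level subtracted.

    Zero-phase high-pass filtering centres each lead over the whole record,
    which leaves the flat segments of a beat at a non-zero offset; the vector
    magnitude would then sit on a pedestal that biases threshold crossings
    and the tangent projection.  The terminal 50 ms of the beat window are
    electrically quiet, so their mean is the per-lead isoelectric level.
    """
    tail = mb.beat[:, -50:].mean(axis=1, keepdims=True)
    return mb.beat - tail


def _threshold_crossing_back(mag_s, start, thr, run=5):
    """Last index before `start` where the signal stays below thr for `run` samples."""
    below = mag_s < thr
    count = 0
    for i in range(start, -1, -1):
        count = count + 1 if below[i] else 0
        if count >= run:
            return i + run - 1
    return 0


def _threshold_crossing_fwd(mag_s, start, thr, run=30):
    below = mag_s < thr
    count = 0
    for i in range(start, len(mag_s)):
        count = count + 1 if below[i] else 0
        if count >= run:
            return i - run + 1
    return len(mag_s) - 1


def delineate(
    mb: MedianBeat,
    overrides: dict[str, float] | None = None,
    qrs_rel_threshold: float = 0.05,
) -> Delineation:
    """Automatic fiducials on the vector magnitude, with manual overrides.

    QRS onset and offset are threshold crossings of the smoothed magnitude at
    ``qrs_rel_threshold`` of the R amplitude above baseline, searched backward
    and forward from the R peak (crossings must be sustained so that brief
    within-QRS dips are skipped).  The T offset uses the tangent method: the
    steepest descending tangent of the T limb is extrapolated to the baseline
    level, the baseline being the mean of the terminal 50 ms of the window.
    Any override replaces the corresponding automatic value verbatim.
    """
    overrides = dict(overrides or {})
    bad = set(overrides) - {"qrs_on", "qrs_off", "t_off"}
    if bad:
        raise DelineationError(f"unknown override fields: {sorted(bad)}")

    mag = vector_magnitude(_baseline_corrected(mb))
    mag_s = _smooth_rms(mag)
    n = len(mag_s)
    r = mb.r_index
    lo, hi = max(r - 60, 0), min(r + 60, n)
    r_peak_idx = lo + int(np.argmax(mag_s[lo:hi]))
    peak = mag_s[r_peak_idx]

    base_n = max(min(150, r - 120), 20)
    baseline = float(np.mean(mag_s[:base_n]))
    noise_est = float(np.std(mag_s[:base_n]))
    if peak - baseline < max(5 * noise_est, 20.0):
        raise DelineationError("QRS magnitude indistinguishable from noise floor")

    thr = baseline + qrs_rel_threshold * (peak - baseline)
    qrs_on = float(_threshold_crossing_back(mag_s, r_peak_idx, thr) + 1)
    qrs_off = float(_threshold_crossing_fwd(mag_s, r_peak_idx, thr) - 1)

    # --- T wave: peak then tangent-method offset -------------------------
    t_search_start = int(qrs_off) + 20
    t_end_guard = n - 5
    if t_search_start >= t_end_guard:
        raise DelineationError("no room for a T wave after the QRS offset")
    t_seg = mag_s[t_search_start:t_end_guard]
    t_peak_idx = t_search_start + int(np.argmax(t_seg))
    tail = mag_s[max(n - 50, 0) :]
    t_baseline = float(np.mean(tail))
    if mag_s[t_peak_idx] - t_baseline < max(3 * noise_est, 10.0):
        raise DelineationError("T wave magnitude below the noise floor")

    grad = np.gradient(mag_s)
    limb = grad[t_peak_idx:t_end_guard]
    if len(limb) < 5:
        raise DelineationError("T descending limb too short for the tangent method")
    i_star = t_peak_idx + int(np.argmin(limb))
    slope = grad[i_star]
    if slope >= 0:
        raise DelineationError("no descending T limb found")
    t_off = float(i_star + (mag_s[i_star] - t_baseline) / (-slope))
    t_off = min(t_off, float(n - 1))

    fid = {"qrs_on": qrs_on, "qrs_off": qrs_off, "t_off": t_off}
    fid.update(overrides)
    source = "manual" if overrides else "automatic"
    for name, v in fid.items():
        if not 0 <= v <= n - 1:
            raise DelineationError(f"{name}={v} outside the beat window [0, {n - 1}]")
    return Delineation(
        qrs_on=fid["qrs_on"], qrs_off=fid["qrs_off"], t_off=fid["t_off"], source=source
    )


# ---------------------------------------------------------------------------
# Scalar measurements
# ---------------------------------------------------------------------------


def fridericia_qtc(qt_ms: float, mean_rr_ms: float) -> float:
    """Fridericia rate correction: QT divided by the cube root of RR in seconds."""
    return qt_ms / (mean_rr_ms / 1000.0) ** (1.0 / 3.0)


def measure_intervals(
    ann: BeatAnnotations, mb: MedianBeat, d: Delineation
) -> EcgMeasurements:
    """Derive HR, QRS duration, QT, Fridericia QTc, T peak and TpTe.

    The T peak is the argmax of the raw vector magnitude on (qrs_off, t_off];
    argmax ties break toward the earliest sample.
    """
    mean_rr = ann.mean_rr_ms
    heart_rate = 60000.0 / mean_rr
    qrs_duration = d.qrs_off - d.qrs_on
    qt = d.t_off - d.qrs_on
    mag = vector_magnitude(_baseline_corrected(mb))
    i0, i1 = int(np.floor(d.qrs_off)) + 1, min(int(np.ceil(d.t_off)) + 1, len(mag))
    if i1 <= i0:
        raise DelineationError("empty T window")
    t_peak = float(i0 + np.argmax(mag[i0:i1]))
    flags: list[str] = []
    if t_peak <= i0 or t_peak >= i1 - 1:
        flags.append("t_peak_at_window_boundary")
    return EcgMeasurements(
        heart_rate=heart_rate,
        mean_rr=mean_rr,
        qrs_duration=qrs_duration,
        qt=qt,
        qtc_fridericia=fridericia_qtc(qt, mean_rr),
        t_peak=t_peak,
        tpte=d.t_off - t_peak,
        flags=tuple(flags),
    )
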