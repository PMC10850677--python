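"""SVD loop decomposition, non-planarity percentages and the spatial QRS-T angle.

A windowed median-beat segment (leads x time, microvolts, referenced to the
isoelectric level at QRS onset) is factored by singular value decomposition.
The first two components span the main plane of vector-loop movement; the
third, orthogonal component carries the signal that twists the loop out of
that plane.  The non-planarity index expresses the relative extent of this
third component as a percentage.  Three normalisation conventions are
available and always recorded in the result:

* ``first3_energy`` (default): ``100 * s3^2 / (s1^2 + s2^2 + s3^2)`` — the
  out-of-plane share of the energy of the 3-D loop itself;
* ``total_energy``:  ``100 * s3^2 / sum_i s_i^2``;
* ``amplitude``:     ``100 * s3 / (s1 + s2 + s3)``.

The spatial QRS-T angle is the angle between the time-integral (area)
vectors of the QRS and T loops, both expressed in the 3-D principal space of
the full QRS-onset-to-T-offset segment, reported in degrees within [0, 180].
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .beat_pipeline import Delineation, MedianBeat
from .ecg_io import BELT3, FULL8, INDEPENDENT_LEADS, LeadSetTag
from .errors import DegenerateSegmentError, LeadSetError, WindowError

CONVENTIONS = ("first3_energy", "total_energy", "amplitude")
MIN_WINDOW_SAMPLES = 20


@dataclass(frozen=True)
class SvdLoopDecomposition:
    """Full SVD of one windowed beat segment.

    ``lead_basis`` holds one orthonormal lead-space vector per component
    (columns); ``component_courses`` the corresponding time courses scaled by
    their singular values, so ``lead_basis @ component_courses`` reconstructs
    the segment.
    """

    singular_values: np.ndarray
    lead_basis: np.ndarray  # [n_leads x n_components]
    component_courses: np.ndarray  # [n_components x n_samples]
    window: str  # "QRS", "T" or "QRST"
    lead_set: LeadSetTag | None = None

    @property
    def n_components(self) -> int:
        return len(self.singular_values)

    def energy(self) -> float:
        return float(np.sum(np.square(self.singular_values)))


@dataclass(frozen=True)
class PlanarityResult:
    """Non-planarity percentage of one loop under one convention."""

    non_planarity_percent: float
    window: str
    lead_set: LeadSetTag
    convention: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.non_planarity_percent <= 100.0:
            raise DegenerateSegmentError(
                f"non-planarity {self.non_planarity_percent} outside [0, 100]"
            )


@dataclass(frozen=True)
class QrstAngle:
    degrees: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.degrees <= 180.0:
            raise DegenerateSegmentError(f"angle {self.degrees} outside [0, 180]")


def extract_window(mb: MedianBeat, d: Delineation, which: str) -> np.ndarray:
    """Cut the QRS or T segment from a median beat, isoelectric-referenced.

    The QRS window spans QRS onset to QRS offset; the T window spans QRS
    offset to T offset (the ST segment is part of the T window).  Both bounds
    are inclusive.  Every lead is referenced to its amplitude at QRS onset,
    the isoelectric point of the beat.
    """
    if which not in ("QRS", "T"):
        raise WindowError(f"unknown window {which!r}")
    on = int(round(d.qrs_on))
    off = int(round(d.qrs_off))
    t_end = int(round(d.t_off))
    i0, i1 = (on, off) if which == "QRS" else (off, t_end)
    if i1 - i0 + 1 < MIN_WINDOW_SAMPLES:
        raise WindowError(
            f"{which} window of {i1 - i0 + 1} samples is shorter than "
            f"{MIN_WINDOW_SAMPLES}"
        )
    if not (0 <= i0 < i1 < mb.n_samples):
        raise WindowError(f"{which} window [{i0}, {i1}] outside the beat")
    iso = mb.beat[:, on][:, None]
    return mb.beat[:, i0 : i1 + 1] - iso


def decompose(
    segment: np.ndarray, lead_set: LeadSetTag | None = None, window: str = "QRS"
) -> SvdLoopDecomposition:
    """Full SVD of a segment; components ordered by decreasing singular value."""
    seg = np.asarray(segment, dtype=float)
    if seg.ndim != 2 or seg.shape[0] < 3:
        raise DegenerateSegmentError("segment must be [>=3 leads x time]")
    if not np.isfinite(seg).all():
        raise DegenerateSegmentError("segment contains non-finite values")
    if not np.any(seg):
        raise DegenerateSegmentError("all-zero segment has no loop")
    u, s, vt = np.linalg.svd(seg, full_matrices=False)
    return SvdLoopDecomposition(
        singular_values=s,
        lead_basis=u,
        component_courses=s[:, None] * vt,
        window=window,
        lead_set=lead_set,
    )


def non_planarity(
    dec: SvdLoopDecomposition, convention: str = "first3_energy"
) -> PlanarityResult:
    """Percentage of the loop carried by the third (out-of-plane) component."""
    if convention not in CONVENTIONS:
        raise WindowError(f"unknown convention {convention!r}; pick from {CONVENTIONS}")
    s = dec.singular_values
    if dec.n_components < 3:
        raise DegenerateSegmentError("need at least 3 components for non-planarity")
    if s[0] <= 0:
        raise DegenerateSegmentError("zero leading singular value")
    if convention == "first3_energy":
        value = 100.0 * s[2] ** 2 / float(np.sum(s[:3] ** 2))
    elif convention == "total_energy":
        value = 100.0 * s[2] ** 2 / float(np.sum(s**2))
    else:  # amplitude
        value = 100.0 * s[2] / float(np.sum(s[:3]))
    return PlanarityResult(
        non_planarity_percent=float(value),
        window=dec.window,
        lead_set=dec.lead_set if dec.lead_set is not None else FULL8,
        convention=convention,
    )


def _belt_from_full8(beat: np.ndarray, leads: tuple[str, ...]) -> np.ndarray:
    idx = {l: k for k, l in enumerate(leads)}
    missing = [l for l in ("V1", "V2", "V5", "V6") if l not in idx]
    if missing:
        raise LeadSetError(f"belt derivation needs precordials, missing {missing}")
    v1, v2, v5, v6 = (beat[idx[l]] for l in ("V1", "V2", "V5", "V6"))
    return np.vstack([v2 - v1, v5 - v2, v6 - v5])


@dataclass(frozen=True)
class PlanarityPanel:
    """The study's four non-planarity values for one recording."""

    qrs_npl_8: PlanarityResult
    t_npl_8: PlanarityResult
    qrs_npl_3: PlanarityResult
    t_npl_3: PlanarityResult
    convention: str

    def to_dict(self) -> dict:
        return {
            "qrs_npl_8": self.qrs_npl_8.non_planarity_percent,
            "t_npl_8": self.t_npl_8.non_planarity_percent,
            "qrs_npl_3": self.qrs_npl_3.non_planarity_percent,
            "t_npl_3": self.t_npl_3.non_planarity_percent,
            "convention": self.convention,
        }


def planarity_panel(
    mb: MedianBeat, d: Delineation, convention: str = "first3_energy"
) -> PlanarityPanel:
    """QRS and T non-planarity on the 8 independent leads and the 3 belt leads.

    The median beat must carry the full independent lead set; the belt-lead
    beat is derived from it by the precordial differences.  All four values
    use the same convention and the same delineation.
    """
    missing = [l for l in INDEPENDENT_LEADS if l not in mb.leads]
    if missing:
        raise LeadSetError(f"panel needs leads {INDEPENDENT_LEADS}, missing {missing}")
    order = [mb.leads.index(l) for l in INDEPENDENT_LEADS]
    full_beat = mb.beat[order]
    belt_beat = _belt_from_full8(full_beat, INDEPENDENT_LEADS)

    results = {}
    for tag, beat in ((FULL8, full_beat), (BELT3, belt_beat)):
        sub = MedianBeat(
            beat=beat,
            r_index=mb.r_index,
            n_beats_used=mb.n_beats_used,
            leads=tag.leads,
            mean_rr_ms=mb.mean_rr_ms,
        )
        for which in ("QRS", "T"):
            seg = extract_window(sub, d, which)
            dec = decompose(seg, lead_set=tag, window=which)
            results[(tag.tag, which)] = non_planarity(dec, convention)
    return PlanarityPanel(
        qrs_npl_8=results[("FULL8", "QRS")],
        t_npl_8=results[("FULL8", "T")],
        qrs_npl_3=results[("BELT3", "QRS")],
        t_npl_3=results[("BELT3", "T")],
        convention=convention,
    )


def qrs_t_angle(mb: MedianBeat, d: Delineation) -> QrstAngle:
    """Spatial QRS-T angle from area vectors in the beat's 3-D principal space.

    The full QRS-onset-to-T-offset segment is decomposed once; the QRS and T
    windows are projected onto its first three components, each window is
    summed over time into an area vector, and the angle between the two area
    vectors is returned in degrees.
    """
    on, t_end = int(round(d.qrs_on)), int(round(d.t_off))
    iso = mb.beat[:, on][:, None]
    full_seg = mb.beat[:, on : t_end + 1] - iso
    dec = decompose(full_seg, window="QRST")
    if dec.n_components < 3:
        raise DegenerateSegmentError("need 3 principal components for the angle")
    u3 = dec.lead_basis[:, :3]
    area = {}
    for which in ("QRS", "T"):
        seg = extract_window(mb, d, which)
        area[which] = (u3.T @ seg).sum(axis=1)
    nq, nt = np.linalg.norm(area["QRS"]), np.linalg.norm(area["T"])
    if nq == 0 or nt == 0:
        raise DegenerateSegmentError("zero-area loop vector")
    cosang = float(np.clip(area["QRS"] @ area["T"] / (nq * nt), -1.0, 1.0))
    return QrstAngle(degrees=float(np.degrees(np.arccos(cosang))))


def export_loop(dec: SvdLoopDecomposition, path) -> None:
    """Write the first-3-component trajectory as a 3-column CSV for 3-D plotting."""
    if dec.n_components < 3:
        raise DegenerateSegmentError("need 3 components to export a 3-D loop")
    traj = dec.component_courses[:3].T
    pd.DataFrame(traj, columns=["c1", "c2", "c3"]).to_csv(
        path, index=False, float_format="%.17g"
    )
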