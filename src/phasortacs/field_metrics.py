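"""Evaluation of the achieved cortical phasor field.

The achieved field of a montage is the complex superposition of the real
lead-field columns weighted by the complex return currents.  Per ROI the
report gives the peak amplitude E_max, the half-maximum element set
(amplitude >= E_max / 2 within the ROI), and the stimulation phase
defined as the circular median phase over that set.  Phase leads between
ROIs and their absolute / relative errors against the desired delays
follow the convention lead(ref, other) = wrap(phi_other - phi_ref): a
positive lead means the reference region leads the other.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError
from .fem_forward import LeadField
from .headmodel import RoiPatch
from .phasor_optimize import ComplexMontage, PhasorTarget, wrap_deg

#: below this achieved absolute error (deg) a zero desired delay counts
#: as matched (relative error 0 instead of undefined)
ZERO_DELAY_TOLERANCE_DEG = 1.0


@dataclass
class PhasorField:
    """Complex normal-component field phasor per cortical element (V/m)."""

    values: np.ndarray  # (n,) complex

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=complex)

    @property
    def n_elements(self) -> int:
        return self.values.shape[0]

    @property
    def amplitude(self) -> np.ndarray:
        return np.abs(self.values)

    @property
    def phase_deg(self) -> np.ndarray:
        return wrap_deg(np.rad2deg(np.angle(self.values)))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "element": np.arange(self.n_elements),
                "amp_Vpm": self.amplitude,
                "phase_deg": self.phase_deg,
            }
        )


def synthesize_field(leadfield: LeadField, montage: ComplexMontage) -> PhasorField:
    """Superpose lead-field columns with the montage's complex return
    currents.  The montage's return order must match the lead field."""
    if montage.return_names != list(leadfield.returns):
        raise ValidationError("montage return order does not match lead field")
    return PhasorField(leadfield.synthesize(montage.return_currents_ma))


def circular_median(angles_deg: np.ndarray) -> float:
    """Circular median: the observed angle minimising the summed absolute
    circular deviation; ties broken by the smallest wrapped angle.

    Robust to wraparound and equal to the ordinary median whenever the
    support spans less than a half circle.
    """
    a = np.asarray(angles_deg, dtype=float)
    if a.size == 0:
        raise ValidationError("no angles given")
    cand = wrap_deg(a)
    dev = np.abs(wrap_deg(cand[:, None] - cand[None, :])).sum(axis=1)
    best = dev.min()
    winners = cand[dev <= best + 1e-12]
    return float(winners.min())


@dataclass
class RoiReport:
    """Per-ROI field summary: peak amplitude, half-maximum set, and the
    circular-median stimulation phase over it."""

    name: str
    e_max: float  # V/m
    halfmax_elements: np.ndarray  # indices into the cortical surface
    median_phase_deg: float  # undefined when phase_defined is False
    phase_defined: bool = True

    def __post_init__(self) -> None:
        self.halfmax_elements = np.asarray(self.halfmax_elements, dtype=np.int64)
        if self.e_max > 0 and self.halfmax_elements.size == 0:
            raise ValidationError("half-maximum set empty despite E_max > 0")


def roi_report(
    fieldv: PhasorField,
    roi: RoiPatch,
    area_weights: np.ndarray | None = None,
) -> RoiReport:
    """Summarise the achieved field over one ROI.

    The half-maximum set holds the ROI elements with amplitude at least
    half the ROI peak; the stimulation phase is the circular median over
    that set (optionally area-weighted by repeating elements in
    proportion to ``area_weights``).
    """
    idx = roi.elements
    if idx.max(initial=-1) >= fieldv.n_elements:
        raise ValidationError(f"ROI {roi.name!r} outside the field")
    amp = fieldv.amplitude[idx]
    e_max = float(amp.max())
    if e_max == 0.0:
        return RoiReport(roi.name, 0.0, np.empty(0, dtype=np.int64),
                         float("nan"), phase_defined=False)
    half = idx[amp >= 0.5 * e_max]
    phases = fieldv.phase_deg[half]
    if area_weights is not None:
        w = np.asarray(area_weights, dtype=float)[half]
        reps = np.maximum(1, np.round(w / w.min()).astype(int))
        phases = np.repeat(phases, reps)
    return RoiReport(roi.name, e_max, half, circular_median(phases))


def lead_angle(report_ref, report_other) -> float:
    """wrap(phi_other - phi_ref) in (-180, 180]; positive means the
    reference region leads.  Accepts RoiReports or phase values in
    degrees."""
    def phase_of(r):
        if isinstance(r, RoiReport):
            if not r.phase_defined:
                raise ValidationError(f"phase undefined for ROI {r.name!r}")
            return r.median_phase_deg
        return float(r)

    return wrap_deg(phase_of(report_other) - phase_of(report_ref))


def phase_error(
    achieved_deg: float,
    desired_deg: float,
    zero_tolerance_deg: float = ZERO_DELAY_TOLERANCE_DEG,
) -> tuple[float, float]:
    """Absolute (degrees) and relative (%) error of an achieved phase
    delay.  The relative error is absolute/|desired|*100; for a zero
    desired delay it is 0 when the absolute error is within
    ``zero_tolerance_deg`` and NaN (flagged undefined) otherwise."""
    absolute = abs(wrap_deg(achieved_deg - desired_deg))
    if desired_deg == 0:
        relative = 0.0 if absolute < zero_tolerance_deg else float("nan")
    else:
        relative = absolute / abs(desired_deg) * 100.0
    return absolute, relative


@dataclass
class DelayReport:
    """Achieved vs desired inter-ROI phase delays, referenced to the
    target's reference ROI."""

    reference: str
    rows: pd.DataFrame = field(default_factory=pd.DataFrame)

    def to_json(self, path) -> None:
        Path(path).write_text(
            json.dumps(
                {"reference": self.reference,
                 "rows": self.rows.to_dict(orient="records")},
                indent=1,
            )
        )


def evaluate_montage(
    leadfield: LeadField,
    montage: ComplexMontage,
    target: PhasorTarget,
    area_weighted: bool = False,
) -> tuple[PhasorField, list[RoiReport], DelayReport]:
    """Synthesize the achieved field and compute all per-ROI and
    inter-ROI metrics for a target."""
    fieldv = synthesize_field(leadfield, montage)
    weights = leadfield.element_areas if area_weighted else None
    reports = [roi_report(fieldv, roi, weights) for roi in target.rois]
    ref = reports[target.reference]
    recs = []
    for roi, rep, desired in zip(target.rois, reports, target.phases_deg):
        if rep is ref:
            continue
        achieved = lead_angle(ref, rep)
        abs_err, rel_err = phase_error(achieved, desired)
        recs.append(
            {
                "roi": roi.name,
                "e_max_Vpm": rep.e_max,
                "median_phase_deg": rep.median_phase_deg,
                "achieved_lead_deg": achieved,
                "desired_lead_deg": desired,
                "abs_error_deg": abs_err,
                "rel_error_pct": rel_err,
            }
        )
    delay = DelayReport(ref.name, pd.DataFrame(recs))
    return fieldv, reports, delay
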