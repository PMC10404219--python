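"""Complex least-squares montage optimization.

A multi-site multi-phase montage is a set of sinusoidal injection
currents at one carrier frequency, represented as phasors x_k =
|x_k| exp(j phi_k).  The desired cortical field is a complex vector b
with A exp(j phi) on each ROI's elements and zero elsewhere; the lead
field A_lf (real, since each pair solve is electrostatic) maps return
currents to the achieved normal field, so the optimal returns solve

    x_ls = argmin_x || b - A_lf x ||_2   (+ ridge ||x||_2 if requested).

Because the matrix is real, the real and imaginary parts decouple into
two independent real least-squares problems.  The active electrode
closes the circuit (its current is minus the sum of the returns) and a
uniform scale factor enforces the per-electrode safety limits (2 mA per
return, 4 mA on the active electrode) without touching any phase.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.linalg

from .errors import ValidationError
from .fem_forward import LeadField
from .headmodel import RoiPatch

DEFAULT_AMPLITUDE = 0.3  # V/m, the default desired field amplitude
RETURN_LIMIT_MA = 2.0
ACTIVE_LIMIT_MA = 4.0
CONDITION_FALLBACK = 1e10  # switch to truncated solve beyond this


def wrap_deg(angle):
    """Wrap angle(s) in degrees into (-180, 180]."""
    a = np.asarray(angle, dtype=float)
    wrapped = -((-a + 180.0) % 360.0 - 180.0)
    out = np.where(wrapped == -180.0, 180.0, wrapped)
    return float(out) if np.isscalar(angle) or out.ndim == 0 else out


@dataclass
class PhasorTarget:
    """Desired per-ROI field phasors.

    The reference ROI (index ``reference``) carries phase 0 by
    convention; a positive phase on another ROI means the reference
    region leads it.
    """

    rois: list[RoiPatch]
    amplitudes: list[float] = None
    phases_deg: list[float] = None
    reference: int = 0

    def __post_init__(self) -> None:
        n = len(self.rois)
        if n == 0:
            self.amplitudes = list(self.amplitudes or [])
            self.phases_deg = list(self.phases_deg or [])
            return
        if self.amplitudes is None:
            self.amplitudes = [DEFAULT_AMPLITUDE] * n
        if self.phases_deg is None:
            self.phases_deg = [0.0] * n
        self.amplitudes = [float(a) for a in self.amplitudes]
        self.phases_deg = [wrap_deg(p) for p in self.phases_deg]
        if len(self.amplitudes) != n or len(self.phases_deg) != n:
            raise ValidationError("amplitudes/phases must match ROI count")
        if any(a <= 0 for a in self.amplitudes):
            raise ValidationError("desired amplitudes must be positive")
        if not 0 <= self.reference < n:
            raise ValidationError("reference ROI index out of range")
        if abs(self.phases_deg[self.reference]) > 1e-12:
            raise ValidationError("reference ROI must have phase 0")
        seen: set[int] = set()
        for roi in self.rois:
            s = set(int(i) for i in roi.elements)
            if seen & s:
                raise ValidationError(f"ROI {roi.name!r} overlaps another ROI")
            seen |= s

    @property
    def names(self) -> list[str]:
        return [r.name for r in self.rois]

    def to_json(self, path) -> None:
        spec = {
            "rois": [
                {
                    "name": r.name,
                    "amplitude_Vpm": a,
                    "phase_deg": p,
                    "elements": np.asarray(r.elements).tolist(),
                    "definition": r.definition,
                }
                for r, a, p in zip(self.rois, self.amplitudes, self.phases_deg)
            ],
            "reference": self.rois[self.reference].name,
        }
        Path(path).write_text(json.dumps(spec))

    @classmethod
    def from_json(cls, path) -> "PhasorTarget":
        spec = json.loads(Path(path).read_text())
        rois, amps, phases = [], [], []
        for r in spec["rois"]:
            rois.append(
                RoiPatch(r["name"], np.asarray(r["elements"], dtype=np.int64),
                         r.get("definition", {}))
            )
            amps.append(r.get("amplitude_Vpm", DEFAULT_AMPLITUDE))
            phases.append(r.get("phase_deg", 0.0))
        ref = [r.name for r in rois].index(spec.get("reference", rois[0].name))
        return cls(rois, amps, phases, ref)


def build_target_vector(leadfield: LeadField, target: PhasorTarget) -> np.ndarray:
    """Complex target b: A cos(phi) + j A sin(phi) on each ROI element,
    zero elsewhere."""
    n = leadfield.n_elements
    b = np.zeros(n, dtype=complex)
    for roi, amp, ph in zip(target.rois, target.amplitudes, target.phases_deg):
        if roi.elements.max(initial=-1) >= n:
            raise ValidationError(
                f"ROI {roi.name!r} references elements beyond the lead field"
            )
        b[roi.elements] = amp * np.exp(1j * np.deg2rad(ph))
    return b


def solve_cls(leadfield, b: np.ndarray, ridge: float = 0.0) -> np.ndarray:
    """Least-squares return currents (mA, complex) for a complex target.

    Solved with a rank-revealing factorisation (LAPACK gelsd), never via
    explicit normal equations; since the lead field is real the real and
    imaginary parts are two independent real problems sharing one
    factorisation.  ``ridge`` adds Tikhonov damping; at ridge 0 a
    truncated solve kicks in automatically when the matrix is
    numerically rank-deficient (condition number beyond 1e10).
    """
    A = leadfield.matrix if isinstance(leadfield, LeadField) else np.asarray(leadfield)
    b = np.asarray(b, dtype=complex)
    if A.ndim != 2 or A.shape[1] < 1:
        raise ValidationError("lead field must have at least one column")
    if b.shape != (A.shape[0],):
        raise ValidationError("target length must match lead-field rows")
    if not (np.all(np.isfinite(A)) and np.all(np.isfinite(b.view(float)))):
        raise ValidationError("non-finite entries in lead field or target")
    if ridge < 0:
        raise ValidationError("ridge must be non-negative")
    rhs = np.column_stack([b.real, b.imag])
    if ridge > 0:
        A = np.vstack([A, np.sqrt(ridge) * np.eye(A.shape[1])])
        rhs = np.vstack([rhs, np.zeros((A.shape[1], 2))])
    sol, _, rank, sv = scipy.linalg.lstsq(
        A, rhs, cond=1.0 / CONDITION_FALLBACK, lapack_driver="gelsd"
    )
    return sol[:, 0] + 1j * sol[:, 1]


@dataclass
class ComplexMontage:
    """Per-electrode complex injection currents (mA) at one carrier
    frequency.

    Only the return currents are stored; the active electrode's current
    is derived as minus their sum, so Kirchhoff's current law holds
    exactly (to the bit) under any uniform scaling.
    """

    active: str
    return_names: list[str]  # lead-field column order
    return_currents_ma: np.ndarray  # (n_returns,) complex
    frequency_hz: float = 80.0
    scale: float = 1.0  # applied safety scale factor
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.return_currents_ma = np.asarray(self.return_currents_ma,
                                             dtype=complex)
        if len(self.return_names) != len(self.return_currents_ma):
            raise ValidationError("names/currents length mismatch")
        if self.active in self.return_names:
            raise ValidationError("active electrode cannot also be a return")
        if not 0 < self.scale <= 1:
            raise ValidationError("scale factor must be in (0, 1]")

    @property
    def names(self) -> list[str]:
        return [self.active] + list(self.return_names)

    @property
    def active_current_ma(self) -> complex:
        return -complex(self.return_currents_ma.sum())

    @property
    def currents_ma(self) -> np.ndarray:
        return np.concatenate(
            [[self.active_current_ma], self.return_currents_ma]
        )

    @property
    def amplitudes_ma(self) -> np.ndarray:
        return np.abs(self.currents_ma)

    @property
    def phases_deg(self) -> np.ndarray:
        return wrap_deg(np.rad2deg(np.angle(self.currents_ma)))

    def kirchhoff_sum(self) -> complex:
        return complex(self.return_currents_ma.sum()) + self.active_current_ma

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "electrode": self.names,
                "amplitude_mA": self.amplitudes_ma,
                "phase_deg": self.phases_deg,
            }
        )

    def to_json(self, path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "active": self.active,
                    "frequency_hz": self.frequency_hz,
                    "scale": self.scale,
                    "electrodes": [
                        {
                            "name": n,
                            "real_mA": float(c.real),
                            "imag_mA": float(c.imag),
                        }
                        for n, c in zip(self.names, self.currents_ma)
                    ],
                    "metadata": self.metadata,
                },
                indent=1,
            )
        )

    @classmethod
    def from_json(cls, path) -> "ComplexMontage":
        spec = json.loads(Path(path).read_text())
        active = spec["active"]
        names, currents = [], []
        for e in spec["electrodes"]:
            if e["name"] == active:
                continue
            names.append(e["name"])
            currents.append(e["real_mA"] + 1j * e["imag_mA"])
        return cls(
            active, names, np.asarray(currents), spec.get("frequency_hz", 80.0),
            spec.get("scale", 1.0), spec.get("metadata", {}),
        )


def complete_montage(
    return_currents: np.ndarray,
    leadfield: LeadField,
    frequency_hz: float = 80.0,
) -> ComplexMontage:
    """Close the circuit: active current = -(sum of return currents)."""
    x = np.asarray(return_currents, dtype=complex)
    if x.shape != (leadfield.n_returns,):
        raise ValidationError("return current length must match lead field")
    return ComplexMontage(
        leadfield.active,
        list(leadfield.returns),
        x,
        frequency_hz=frequency_hz,
    )


def apply_safety_scaling(
    montage: ComplexMontage,
    return_limit_ma: float = RETURN_LIMIT_MA,
    active_limit_ma: float = ACTIVE_LIMIT_MA,
) -> ComplexMontage:
    """Uniformly scale all currents so no return exceeds
    ``return_limit_ma`` and the active electrode stays within
    ``active_limit_ma``.  Phases (and hence the achieved phase map) are
    untouched; the factor is recorded on the montage."""
    if return_limit_ma <= 0 or active_limit_ma <= 0:
        raise ValidationError("current limits must be positive")
    ret_amp = np.abs(montage.return_currents_ma)
    max_ret = float(ret_amp.max(initial=0.0))
    act = abs(montage.active_current_ma)
    s = min(
        1.0,
        return_limit_ma / max_ret if max_ret > 0 else 1.0,
        active_limit_ma / act if act > 0 else 1.0,
    )
    return ComplexMontage(
        montage.active,
        list(montage.return_names),
        s * montage.return_currents_ma,
        montage.frequency_hz,
        scale=montage.scale * s,
        metadata={
            **montage.metadata,
            "return_limit_mA": return_limit_ma,
            "active_limit_mA": active_limit_ma,
        },
    )


def optimize_montage(
    leadfield: LeadField,
    target: PhasorTarget,
    frequency_hz: float = 80.0,
    ridge: float = 0.0,
    return_limit_ma: float = RETURN_LIMIT_MA,
    active_limit_ma: float = ACTIVE_LIMIT_MA,
) -> ComplexMontage:
    """Full pipeline: target vector -> CLS -> montage completion ->
    safety scaling."""
    b = build_target_vector(leadfield, target)
    x = solve_cls(leadfield, b, ridge=ridge)
    montage = complete_montage(x, leadfield, frequency_hz)
    return apply_safety_scaling(montage, return_limit_ma, active_limit_ma)
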