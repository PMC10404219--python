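"""Model/Results interface over the montage optimizer.

``MontageModel`` is built from a lead field and a phasor target (the
data); ``fit()`` runs the complex least-squares optimization, montage
completion and safety scaling, and returns ``MontageResults`` carrying
the per-electrode currents, the achieved cortical phasor field, per-ROI
reports, inter-ROI delay errors, residual diagnostics and a printable
``summary()``.  Waveform simulation and plotting hang off the results.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fem_forward import LeadField
from .field_metrics import (
    DelayReport,
    PhasorField,
    RoiReport,
    evaluate_montage,
)
from .phasor_optimize import (
    ACTIVE_LIMIT_MA,
    RETURN_LIMIT_MA,
    ComplexMontage,
    PhasorTarget,
    apply_safety_scaling,
    build_target_vector,
    complete_montage,
    solve_cls,
)
from .stim_protocol import StimulationPlan, render_waveforms


class MontageModel:
    """Phasor-targeting montage design problem.

    Parameters
    ----------
    leadfield
        Real lead field (V/m per mA) with one column per return electrode.
    target
        Desired per-ROI amplitudes and phases.
    frequency_hz
        Carrier frequency; metadata only, the optimization is frequency
        free under the quasi-static assumption.
    ridge
        Optional Tikhonov damping of the least-squares solve.
    """

    def __init__(
        self,
        leadfield: LeadField,
        target: PhasorTarget,
        frequency_hz: float = 80.0,
        ridge: float = 0.0,
    ) -> None:
        self.leadfield = leadfield
        self.target = target
        self.frequency_hz = float(frequency_hz)
        self.ridge = float(ridge)
        self.b = build_target_vector(leadfield, target)

    @classmethod
    def from_files(
        cls, leadfield_path, target_path, frequency_hz: float = 80.0,
        ridge: float = 0.0,
    ) -> "MontageModel":
        return cls(
            LeadField.load(leadfield_path),
            PhasorTarget.from_json(target_path),
            frequency_hz,
            ridge,
        )

    def fit(
        self,
        return_limit_ma: float = RETURN_LIMIT_MA,
        active_limit_ma: float = ACTIVE_LIMIT_MA,
        area_weighted_median: bool = False,
    ) -> "MontageResults":
        x = solve_cls(self.leadfield, self.b, ridge=self.ridge)
        montage = complete_montage(x, self.leadfield, self.frequency_hz)
        montage = apply_safety_scaling(montage, return_limit_ma, active_limit_ma)
        fieldv, reports, delays = evaluate_montage(
            self.leadfield, montage, self.target, area_weighted_median
        )
        residual = self.b - self.leadfield.matrix @ x
        return MontageResults(
            model=self,
            montage=montage,
            field=fieldv,
            roi_reports=reports,
            delay_report=delays,
            residual_norm=float(np.linalg.norm(residual)),
            target_norm=float(np.linalg.norm(self.b)),
        )


@dataclass
class MontageResults:
    """Fitted montage with achieved-field diagnostics."""

    model: MontageModel
    montage: ComplexMontage
    field: PhasorField
    roi_reports: list[RoiReport]
    delay_report: DelayReport
    residual_norm: float
    target_norm: float

    @property
    def scale(self) -> float:
        return self.montage.scale

    @property
    def currents(self) -> pd.DataFrame:
        return self.montage.to_frame()

    def roi_table(self) -> pd.DataFrame:
        tgt = self.model.target
        return pd.DataFrame(
            {
                "roi": [r.name for r in self.roi_reports],
                "desired_amp_Vpm": tgt.amplitudes,
                "desired_phase_deg": tgt.phases_deg,
                "e_max_Vpm": [r.e_max for r in self.roi_reports],
                "n_halfmax": [len(r.halfmax_elements) for r in self.roi_reports],
                "median_phase_deg": [r.median_phase_deg for r in self.roi_reports],
            }
        )

    def summary(self) -> str:
        m = self.montage
        amp = m.amplitudes_ma
        lines = [
            "Phasor montage optimization results",
            "=" * 51,
            f"electrodes: {len(m.names)} (active {m.active!r})"
            f"   carrier: {m.frequency_hz:g} Hz",
            f"safety scale factor: {m.scale:.4f}"
            f"   max |I| return: {np.abs(m.return_currents_ma).max():.3f} mA"
            f"   active: {abs(m.active_current_ma):.3f} mA",
            f"Kirchhoff sum: {abs(m.kirchhoff_sum()):.2e} mA",
            f"relative residual ||b - Ax|| / ||b||: "
            f"{self.residual_norm / self.target_norm:.3f}"
            if self.target_norm > 0
            else "zero target",
            "",
            "Per-ROI achieved field",
            "-" * 51,
            self.roi_table().to_string(index=False, float_format="%.3f"),
        ]
        if len(self.delay_report.rows):
            lines += [
                "",
                f"Inter-ROI delays (reference {self.delay_report.reference!r})",
                "-" * 51,
                self.delay_report.rows.to_string(
                    index=False, float_format="%.2f"
                ),
            ]
        top = np.argsort(amp)[::-1][:8]
        lines += [
            "",
            "Largest currents",
            "-" * 51,
            pd.DataFrame(
                {
                    "electrode": [m.names[i] for i in top],
                    "amplitude_mA": amp[top],
                    "phase_deg": m.phases_deg[top],
                }
            ).to_string(index=False, float_format="%.3f"),
        ]
        return "\n".join(lines)

    # --------------------------------------------------------- simulation
    def plan(
        self,
        duration_s: float = 600.0,
        ramp_s: float = 30.0,
        sample_rate_hz: float = 10_000.0,
    ) -> StimulationPlan:
        return StimulationPlan(self.montage, duration_s, ramp_s, sample_rate_hz)

    def simulate_waveforms(
        self,
        duration_s: float = 600.0,
        ramp_s: float = 30.0,
        sample_rate_hz: float = 10_000.0,
    ) -> pd.DataFrame:
        return render_waveforms(self.plan(duration_s, ramp_s, sample_rate_hz))

    # ----------------------------------------------------------- plotting
    def plot_field(self, surface=None, kind: str = "amplitude", ax=None):
        """Cortical amplitude or phase map.

        With a ``CorticalSurface`` the map is a 3-D scatter at the element
        centroids; without one it falls back to value-vs-element-index.
        """
        import matplotlib.pyplot as plt

        vals = (
            self.field.amplitude if kind == "amplitude" else self.field.phase_deg
        )
        label = "V/m" if kind == "amplitude" else "degrees"
        if surface is not None:
            if ax is None:
                _, ax = plt.subplots(subplot_kw={"projection": "3d"})
            c = surface.centroids
            sc = ax.scatter(c[:, 0], c[:, 1], c[:, 2], c=vals, s=4)
            plt.colorbar(sc, ax=ax, label=label)
        else:
            if ax is None:
                _, ax = plt.subplots()
            ax.scatter(np.arange(len(vals)), vals, s=2)
            ax.set_xlabel("cortical element")
            ax.set_ylabel(label)
        return ax
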