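"""Electrode layouts on the unit sphere.

Coordinates follow a RAS-like convention: +x right ear, +y nasion (front),
+z vertex.  A layout stores, per electrode, a unit direction from the head
centre plus the disc radius and sponge height in mm; positions on a
particular head are obtained by projecting the direction onto the scalp.

The 61-channel 10-10 layout is generated geometrically: the sagittal
midline chain and the outer 10%-ring carry electrodes at 18 degree steps,
and the lateral electrodes of each coronal row are placed by spherical
interpolation between the row's midline electrode and its ring endpoint.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError

DEFAULT_DISC_RADIUS_MM = 5.0
DEFAULT_HEIGHT_MM = 25.0

#: The eight parietal/occipital electrodes of the bilateral-IPS protocol.
PARIETAL_8 = ("P3", "Pz", "P4", "PO3", "PO4", "PO7", "Oz", "PO8")


@dataclass
class ElectrodeLayout:
    """Named electrode directions with per-electrode disc geometry."""

    names: list[str]
    directions: np.ndarray  # (n, 3) unit vectors
    radii_mm: np.ndarray  # (n,)
    heights_mm: np.ndarray  # (n,)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.directions = np.asarray(self.directions, dtype=float)
        self.radii_mm = np.asarray(self.radii_mm, dtype=float)
        self.heights_mm = np.asarray(self.heights_mm, dtype=float)
        n = len(self.names)
        if len(set(self.names)) != n:
            raise ValidationError("electrode names must be unique")
        if self.directions.shape != (n, 3):
            raise ValidationError("directions must be (n, 3)")
        if np.any(self.radii_mm <= 0) or np.any(self.heights_mm <= 0):
            raise ValidationError("electrode radii and heights must be positive")
        norms = np.linalg.norm(self.directions, axis=1)
        if np.any(norms == 0):
            raise ValidationError("zero-length electrode direction")
        self.directions = self.directions / norms[:, None]

    def __len__(self) -> int:
        return len(self.names)

    def __iter__(self):
        for i, name in enumerate(self.names):
            yield name, self.directions[i], self.radii_mm[i], self.heights_mm[i]

    def subset(self, names: tuple[str, ...] | list[str]) -> "ElectrodeLayout":
        idx = [self.names.index(n) for n in names]
        return ElectrodeLayout(
            [self.names[i] for i in idx],
            self.directions[idx],
            self.radii_mm[idx],
            self.heights_mm[idx],
            dict(self.metadata),
        )

    # ---------------------------------------------------------------- I/O
    def to_csv(self, path_or_buf, scalp_radius_mm: float = 1.0) -> None:
        """Write `name,x,y,z,radius_mm,height_mm` with positions at the
        given scalp radius."""
        pos = self.directions * scalp_radius_mm
        df = pd.DataFrame(
            {
                "name": self.names,
                "x": pos[:, 0],
                "y": pos[:, 1],
                "z": pos[:, 2],
                "radius_mm": self.radii_mm,
                "height_mm": self.heights_mm,
            }
        )
        df.to_csv(path_or_buf, index=False)

    @classmethod
    def from_csv(cls, path_or_buf) -> "ElectrodeLayout":
        """Read a layout table.

        Two dialects are accepted: Cartesian (`name,x,y,z[,radius_mm,
        height_mm]`) and spherical (`name,theta_deg,phi_deg[,...]`) with
        theta the polar angle from +z and phi the azimuth from +x toward +y.
        """
        df = pd.read_csv(path_or_buf)
        cols = set(df.columns)
        if {"x", "y", "z"} <= cols:
            directions = df[["x", "y", "z"]].to_numpy(float)
        elif {"theta_deg", "phi_deg"} <= cols:
            th = np.deg2rad(df["theta_deg"].to_numpy(float))
            ph = np.deg2rad(df["phi_deg"].to_numpy(float))
            directions = np.column_stack(
                [np.sin(th) * np.cos(ph), np.sin(th) * np.sin(ph), np.cos(th)]
            )
        else:
            raise ValidationError(
                "layout CSV needs columns x,y,z or theta_deg,phi_deg"
            )
        n = len(df)
        radii = (
            df["radius_mm"].to_numpy(float)
            if "radius_mm" in cols
            else np.full(n, DEFAULT_DISC_RADIUS_MM)
        )
        heights = (
            df["height_mm"].to_numpy(float)
            if "height_mm" in cols
            else np.full(n, DEFAULT_HEIGHT_MM)
        )
        return cls(list(df["name"].astype(str)), directions, radii, heights)


def _sph(theta_deg: float, phi_deg: float) -> np.ndarray:
    th, ph = np.deg2rad(theta_deg), np.deg2rad(phi_deg)
    return np.array(
        [np.sin(th) * np.cos(ph), np.sin(th) * np.sin(ph), np.cos(th)]
    )


def _slerp(a: np.ndarray, b: np.ndarray, t: float) -> np.ndarray:
    """Great-circle interpolation between unit vectors."""
    omega = np.arccos(np.clip(a @ b, -1.0, 1.0))
    if omega < 1e-12:
        return a.copy()
    return (np.sin((1 - t) * omega) * a + np.sin(t * omega) * b) / np.sin(omega)


def standard_10_10(
    disc_radius_mm: float = DEFAULT_DISC_RADIUS_MM,
    height_mm: float = DEFAULT_HEIGHT_MM,
) -> ElectrodeLayout:
    """The 61-channel extended 10-20 ("10-10") layout used by default.

    Midline electrodes sit on the nasion-inion arc at 18 degree steps; the
    outer ring (through Fp1, F7, T7, ... at 72 degrees inclination) carries
    the remaining 10-20 electrodes at 18 degree azimuthal steps; in-between
    electrodes of each coronal row interpolate between the midline and ring
    electrodes of that row.
    """
    pos: dict[str, np.ndarray] = {}

    # Sagittal midline, front (phi=90) to back (phi=270).
    for name, theta, phi in [
        ("Fpz", 72, 90), ("AFz", 54, 90), ("Fz", 36, 90), ("FCz", 18, 90),
        ("Cz", 0, 90), ("CPz", 18, 270), ("Pz", 36, 270), ("POz", 54, 270),
        ("Oz", 72, 270),
    ]:
        pos[name] = _sph(theta, phi)

    # Outer ring at 72 deg inclination, 18 deg azimuthal steps.
    ring_left = ["Fp1", "AF7", "F7", "FT7", "T7", "TP7", "P7", "PO7", "O1"]
    ring_right = ["Fp2", "AF8", "F8", "FT8", "T8", "TP8", "P8", "PO8", "O2"]
    for k, (ln, rn) in enumerate(zip(ring_left, ring_right), start=1):
        pos[ln] = _sph(72, 90 + 18 * k)
        pos[rn] = _sph(72, 90 - 18 * k)

    # Coronal rows: slerp from the midline electrode to the ring endpoint.
    rows = [
        ("AFz", "AF7", "AF8", [("AF3", "AF4", 0.5)]),
        ("Fz", "F7", "F8", [("F1", "F2", 0.25), ("F3", "F4", 0.5), ("F5", "F6", 0.75)]),
        ("FCz", "FT7", "FT8",
         [("FC1", "FC2", 0.25), ("FC3", "FC4", 0.5), ("FC5", "FC6", 0.75)]),
        ("Cz", "T7", "T8", [("C1", "C2", 0.25), ("C3", "C4", 0.5), ("C5", "C6", 0.75)]),
        ("CPz", "TP7", "TP8",
         [("CP1", "CP2", 0.25), ("CP3", "CP4", 0.5), ("CP5", "CP6", 0.75)]),
        ("Pz", "P7", "P8", [("P1", "P2", 0.25), ("P3", "P4", 0.5), ("P5", "P6", 0.75)]),
        ("POz", "PO7", "PO8", [("PO3", "PO4", 0.5)]),
    ]
    for mid, lend, rend, inner in rows:
        for ln, rn, t in inner:
            pos[ln] = _slerp(pos[mid], pos[lend], t)
            pos[rn] = _slerp(pos[mid], pos[rend], t)

    names = sorted(pos)  # deterministic order
    directions = np.array([pos[n] for n in names])
    n = len(names)
    return ElectrodeLayout(
        names,
        directions,
        np.full(n, disc_radius_mm),
        np.full(n, height_mm),
        metadata={"scheme": "10-10", "n": n},
    )


def parietal_8(
    disc_radius_mm: float = DEFAULT_DISC_RADIUS_MM,
    height_mm: float = DEFAULT_HEIGHT_MM,
) -> ElectrodeLayout:
    """Eight-electrode parieto-occipital montage preset (P3, Pz, P4, PO3,
    PO4, PO7, Oz, PO8)."""
    full = standard_10_10(disc_radius_mm, height_mm)
    return full.subset(PARIETAL_8)


def layout_from_string(csv_text: str) -> ElectrodeLayout:
    return ElectrodeLayout.from_csv(io.StringIO(csv_text))
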