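"""Detector geometry, energy binning and resolution broadening parameters.

The detector is modelled as a bare right circular cylinder of scintillator
(NaI(Tl) by default, 5.08 x 5.08 cm diameter x height) exposed either to a
parallel photon beam at a fixed incidence angle, or to a fully isotropic
field.  Energy deposition is recorded on a linear pulse-height grid; the
finite scintillator resolution is described by the usual three-parameter
FWHM model ``FWHM(E) = a + b*sqrt(E + c*E**2)`` with ``FWHM = 2.36 * sigma``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DetectorGeometry",
    "EnergyGrid",
    "GeometryCondition",
    "BroadeningParams",
    "projected_area",
]


@dataclass(frozen=True)
class DetectorGeometry:
    """Right circular cylinder of scintillator crystal.

    Parameters are in cm and g/cm^3.  The default is a 2x2 inch NaI(Tl)
    crystal at a bulk density of 3.6 g/cm^3.
    """

    diameter_cm: float = 5.08
    height_cm: float = 5.08
    density_g_cm3: float = 3.6
    label: str = "NaI(Tl) 5.08x5.08 cm"

    def __post_init__(self) -> None:
        if self.diameter_cm <= 0 or self.height_cm <= 0:
            raise ValueError("cylinder dimensions must be positive")
        if self.density_g_cm3 <= 0:
            raise ValueError("crystal density must be positive")

    @property
    def radius_cm(self) -> float:
        return 0.5 * self.diameter_cm

    @property
    def volume_cm3(self) -> float:
        return np.pi * self.radius_cm**2 * self.height_cm


def projected_area(geom: DetectorGeometry, angle_deg: float) -> float:
    """Silhouette area (cm^2) of the cylinder seen from ``angle_deg``.

    ``angle_deg`` is measured from the cylinder axis: 0 deg is end-on (the
    disc, ``pi r^2``), 90 deg is side-on (the ``d x h`` rectangle).  For
    intermediate angles the silhouette is the sum of the projected disc and
    the projected rectangle::

        A(alpha) = pi r^2 cos(alpha) + d h sin(alpha)

    This is what makes a low-energy photon flux "see" more crystal at
    oblique incidence, the dominant cause of geometry dependence of the
    spectrum-to-dose conversion at low energy.
    """
    if not 0.0 <= angle_deg <= 90.0:
        raise ValueError(f"incidence angle must be in [0, 90] deg, got {angle_deg}")
    a = np.deg2rad(angle_deg)
    return float(
        np.pi * geom.radius_cm**2 * np.cos(a)
        + geom.diameter_cm * geom.height_cm * np.sin(a)
    )


class EnergyGrid:
    """Linear (or user supplied) pulse-height energy grid in keV.

    ``edges`` has length ``n_channels + 1`` and must be strictly increasing;
    channel centers are bin midpoints.
    """

    def __init__(self, edges: np.ndarray):
        edges = np.asarray(edges, dtype=float)
        if edges.ndim != 1 or edges.size < 2:
            raise ValueError("edges must be a 1-D array of at least two energies")
        if not np.all(np.diff(edges) > 0):
            raise ValueError("channel edges must be strictly increasing")
        self.edges = edges

    @classmethod
    def linear(cls, n_channels: int = 869, e_min: float = 0.0, e_max: float = 3100.0) -> "EnergyGrid":
        if n_channels < 1:
            raise ValueError("need at least one channel")
        return cls(np.linspace(e_min, e_max, n_channels + 1))

    @property
    def n_channels(self) -> int:
        return self.edges.size - 1

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    @property
    def widths(self) -> np.ndarray:
        return np.diff(self.edges)

    def channel_of(self, energy_keV: float) -> int:
        """Index of the channel containing ``energy_keV``."""
        if energy_keV < self.edges[0] or energy_keV > self.edges[-1]:
            raise ValueError(
                f"energy {energy_keV} keV outside grid [{self.edges[0]}, {self.edges[-1]}]"
            )
        idx = int(np.searchsorted(self.edges, energy_keV, side="right") - 1)
        return min(idx, self.n_channels - 1)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, EnergyGrid) and np.array_equal(self.edges, other.edges)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"EnergyGrid(n_channels={self.n_channels}, "
            f"range=[{self.edges[0]:g}, {self.edges[-1]:g}] keV)"
        )


@dataclass(frozen=True)
class GeometryCondition:
    """Irradiation geometry: a fixed incidence angle or an isotropic field."""

    mode: str = "fixed-angle"
    angle_deg: float | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("fixed-angle", "isotropic"):
            raise ValueError(f"unknown geometry mode {self.mode!r}")
        if self.mode == "fixed-angle":
            if self.angle_deg is None:
                raise ValueError("fixed-angle geometry requires an angle")
            if not 0.0 <= self.angle_deg <= 90.0:
                raise ValueError("incidence angle must be in [0, 90] deg")
        elif self.angle_deg is not None:
            raise ValueError("isotropic geometry takes no angle")

    @classmethod
    def at_angle(cls, angle_deg: float) -> "GeometryCondition":
        return cls(mode="fixed-angle", angle_deg=angle_deg)

    @classmethod
    def isotropic(cls) -> "GeometryCondition":
        return cls(mode="isotropic")

    @property
    def label(self) -> str:
        if self.mode == "isotropic":
            return "iso"
        return f"{self.angle_deg:g}deg"


@dataclass(frozen=True)
class BroadeningParams:
    """Three-parameter Gaussian energy broadening model.

    ``FWHM(E) = a + b*sqrt(E + c*E^2)`` with E in keV; ``a`` in keV,
    ``b`` in keV^(1/2), ``c`` in 1/keV.  ``sigma = FWHM / fwhm_factor`` with
    the conventional factor 2.36.  The defaults give ~7% resolution at
    662 keV, typical of NaI(Tl).
    """

    a: float = 1.0
    b: float = 1.8
    c: float = 0.0
    fwhm_factor: float = 2.36

    def fwhm(self, energy_keV: np.ndarray | float) -> np.ndarray | float:
        e = np.asarray(energy_keV, dtype=float)
        arg = e + self.c * e**2
        if np.any(arg < 0):
            raise ValueError("FWHM argument E + c*E^2 negative on grid")
        out = self.a + self.b * np.sqrt(arg)
        return out if out.ndim else float(out)

    def sigma(self, energy_keV: np.ndarray | float) -> np.ndarray | float:
        return self.fwhm(energy_keV) / self.fwhm_factor
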