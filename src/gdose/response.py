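"""Simplified detector response simulation for a cylindrical scintillator.

This module is a desk-scale substitute for full Monte Carlo photon transport.
For each incident energy E0 and incidence direction it models:

* geometric interception: the beam sees the projected (silhouette) area of
  the cylinder, ``A(alpha)``;
* interaction: exponential attenuation over the mean chord length
  ``V / A(alpha)`` with the total interaction coefficient of the crystal;
* energy deposition, split into a full-energy peak and a single-scatter
  Compton continuum.  Photoelectric and pair events deposit their full
  energy.  Compton events deposit the Klein-Nishina recoil-electron spectrum
  on [0, Compton edge]; for each deposition the scattered photon either
  escapes (continuum count) or is reabsorbed on its way out (attenuation at
  the scattered-photon energy over half the mean chord), in which case the
  event is promoted to the full-energy peak.  This second-order correction is what
  makes the high-energy response approximately volume- rather than
  area-dominated, as observed for real scintillators.

Escape peaks, coherent scattering, housing/reflector transport and
electronics effects are deliberately out of scope.  Columns are normalised
per unit incident fluence, so they carry units of cm^2 and can never exceed
the projected area of the crystal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .attenuation import InteractionTable, load_nai_table
from .detector import (
    BroadeningParams,
    DetectorGeometry,
    EnergyGrid,
    GeometryCondition,
    projected_area,
)
from .spectrum import Spectrum

__all__ = [
    "PhysicsModel",
    "ResponseMatrix",
    "compton_edge",
    "simulate_response",
    "isotropic_response",
    "apply_broadening",
    "make_spectrum",
]

_ELECTRON_REST_KEV = 511.0


def compton_edge(e0_keV: float) -> float:
    """Maximum single-scatter energy deposition 2*E0^2 / (me c^2 + 2*E0)."""
    return 2.0 * e0_keV**2 / (_ELECTRON_REST_KEV + 2.0 * e0_keV)


def klein_nishina_electron_spectrum(e0_keV: float, t_keV: np.ndarray) -> np.ndarray:
    """Unnormalised Klein-Nishina recoil-electron energy distribution.

    Valid for deposited energies ``t_keV`` in [0, compton_edge(e0)); used
    only as a shape, so overall constants are dropped.
    """
    alpha = e0_keV / _ELECTRON_REST_KEV
    s = np.asarray(t_keV, dtype=float) / e0_keV
    out = np.zeros_like(s)
    ok = (s >= 0) & (s < 1.0) & (np.asarray(t_keV) <= compton_edge(e0_keV) + 1e-12)
    ss = s[ok]
    out[ok] = 2.0 + ss**2 / (alpha**2 * (1.0 - ss) ** 2) + ss / (1.0 - ss) * (
        ss - 2.0 / alpha
    )
    return np.clip(out, 0.0, None)


@dataclass(frozen=True)
class PhysicsModel:
    """Interaction data and optional extras for the simplified transport.

    ``backscatter_pedestal`` adds a small constant low-energy pedestal
    (fraction of the interacting counts, spread uniformly below 250 keV)
    mimicking scatter off material behind the crystal; off by default.
    """

    interactions: InteractionTable = field(default_factory=load_nai_table)
    backscatter_pedestal: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.backscatter_pedestal < 1.0:
            raise ValueError("backscatter_pedestal must be in [0, 1)")


@dataclass
class ResponseMatrix:
    """Discretised detector response R(E, E0) per unit incident fluence.

    ``values`` has shape (n_channels, n_source_energies) and units of cm^2:
    expected counts per channel, per unit fluence (1/cm^2) of photons at the
    column's incident energy, under the stored irradiation condition.
    """

    grid: EnergyGrid
    source_energies: np.ndarray
    values: np.ndarray
    condition: GeometryCondition
    broadened: bool = False
    geom: DetectorGeometry = field(default_factory=DetectorGeometry)

    def __post_init__(self) -> None:
        self.source_energies = np.asarray(self.source_energies, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.grid.n_channels, self.source_energies.size):
            raise ValueError("values shape must be (n_channels, n_sources)")
        if np.any(self.values < -1e-12):
            raise ValueError("response matrix entries must be non-negative")
        if not self.broadened:
            # no deposition above the incident energy: channels entirely
            # above E0 must be empty
            for j, e0 in enumerate(self.source_energies):
                above = self.grid.edges[:-1] > e0 + 1e-9
                if np.any(self.values[above, j] > 1e-12):
                    raise ValueError(
                        f"unbroadened column at E0={e0:g} keV deposits above E0"
                    )
        max_area = self._max_area()
        sums = self.values.sum(axis=0)
        if np.any(sums > max_area * (1 + 1e-9)):
            raise ValueError("column sum exceeds the geometric cross-section")

    def _max_area(self) -> float:
        if self.condition.mode == "fixed-angle":
            return projected_area(self.geom, self.condition.angle_deg)
        return max(projected_area(self.geom, a) for a in np.linspace(0, 90, 181))

    def column(self, e0_keV: float) -> np.ndarray:
        j = self.column_index(e0_keV)
        return self.values[:, j]

    def column_index(self, e0_keV: float) -> int:
        idx = np.nonzero(np.isclose(self.source_energies, e0_keV, rtol=1e-9, atol=1e-6))[0]
        if idx.size == 0:
            raise ValueError(f"no response column at E0 = {e0_keV} keV")
        return int(idx[0])


def _column_for_angle(
    geom: DetectorGeometry,
    angle_deg: float,
    e0: float,
    grid: EnergyGrid,
    physics: PhysicsModel,
) -> np.ndarray:
    tab = physics.interactions
    rho = geom.density_g_cm3
    mu_photo = tab.mu_rho(e0, "photo") * rho
    mu_inc = tab.mu_rho(e0, "incoherent") * rho
    mu_pair = tab.mu_rho(e0, "pair") * rho
    mu_tot = mu_photo + mu_inc + mu_pair

    area = projected_area(geom, angle_deg)
    chord = geom.volume_cm3 / area
    p_int = 1.0 - np.exp(-mu_tot * chord)
    n_int = area * p_int  # interacting photons per unit fluence, cm^2

    f_photo = (mu_photo + mu_pair) / mu_tot
    f_compton = mu_inc / mu_tot

    centers = grid.centers
    widths = grid.widths
    edge = compton_edge(e0)
    in_cont = centers <= edge
    w = np.zeros_like(centers)
    if np.any(in_cont):
        w[in_cont] = (
            klein_nishina_electron_spectrum(e0, centers[in_cont]) * widths[in_cont]
        )
    wsum = w.sum()

    col = np.zeros(grid.n_channels)
    f_peak = f_photo
    if wsum > 0:
        w_norm = w[in_cont] / wsum
        # per-deposition escape probability of the scattered photon
        # (energy E0 - T) over half the mean chord; a scattered photon that
        # does not escape is treated as absorbed, promoting the event to
        # the full-energy peak
        e_scatter = np.clip(e0 - centers[in_cont], tab.energies_keV[0], None)
        mu_sc = tab.mu_rho(e_scatter, "total") * rho
        p_escape = np.exp(-mu_sc * 0.5 * chord)
        col[in_cont] += n_int * f_compton * w_norm * p_escape
        f_peak += f_compton * float((w_norm * (1.0 - p_escape)).sum())
    else:
        f_peak += f_compton  # continuum support below the first channel center
    col[grid.channel_of(e0)] += n_int * f_peak

    if physics.backscatter_pedestal > 0:
        ped = physics.backscatter_pedestal * n_int
        sel = (centers < 250.0) & (centers <= e0)
        if np.any(sel):
            col *= 1.0 - physics.backscatter_pedestal
            col[sel] += ped / sel.sum()
    return col


def simulate_response(
    geom: DetectorGeometry,
    condition: GeometryCondition,
    source_energies: np.ndarray,
    grid: EnergyGrid,
    physics: PhysicsModel | None = None,
) -> ResponseMatrix:
    """Unbroadened response matrix for a fixed incidence angle.

    Use :func:`isotropic_response` for an isotropic field.
    """
    if condition.mode != "fixed-angle":
        raise ValueError("simulate_response handles fixed-angle conditions only")
    physics = physics or PhysicsModel()
    source_energies = np.asarray(source_energies, dtype=float)
    if source_energies.size == 0:
        raise ValueError("source_energies must not be empty")
    if np.any(source_energies < grid.edges[0]) or np.any(source_energies > grid.edges[-1]):
        raise ValueError("source energies must lie within the energy grid")

    values = np.column_stack(
        [
            _column_for_angle(geom, condition.angle_deg, e0, grid, physics)
            for e0 in source_energies
        ]
    )
    return ResponseMatrix(
        grid=grid,
        source_energies=source_energies,
        values=values,
        condition=condition,
        broadened=False,
        geom=geom,
    )


def isotropic_response(
    geom: DetectorGeometry,
    source_energies: np.ndarray,
    grid: EnergyGrid,
    physics: PhysicsModel | None = None,
    n_angles: int = 16,
) -> ResponseMatrix:
    """Solid-angle-weighted average of fixed-angle responses.

    The cylinder (without backing structures) is mirror-symmetric about its
    mid-plane and rotationally symmetric about its axis, so the isotropic
    response is the sin(alpha)-weighted average over alpha in [0, 90] deg,
    evaluated with ``n_angles`` Gauss-Legendre nodes.
    """
    if n_angles < 2:
        raise ValueError("isotropic quadrature needs at least 2 angles")
    nodes, weights = np.polynomial.legendre.leggauss(n_angles)
    alpha = 0.25 * np.pi * (nodes + 1.0)  # map [-1,1] -> [0, pi/2]
    w = weights * np.sin(alpha)
    w /= w.sum()

    acc = None
    for ai, wi in zip(np.rad2deg(alpha), w):
        r = simulate_response(
            geom, GeometryCondition.at_angle(float(ai)), source_energies, grid, physics
        )
        acc = wi * r.values if acc is None else acc + wi * r.values
    return ResponseMatrix(
        grid=grid,
        source_energies=np.asarray(source_energies, dtype=float),
        values=acc,
        condition=GeometryCondition.isotropic(),
        broadened=False,
        geom=geom,
    )


def apply_broadening(r: ResponseMatrix, params: BroadeningParams) -> ResponseMatrix:
    """Convolve each column with the energy-dependent Gaussian kernel.

    Counts in a channel at energy Ei are redistributed with a Gaussian of
    ``sigma(Ei) = FWHM(Ei) / fwhm_factor``.  Each kernel column is
    normalised over the grid, so total counts are conserved to floating
    point accuracy.
    """
    if r.broadened:
        raise ValueError("response matrix is already broadened")
    centers = r.grid.centers
    fwhm = np.asarray(params.fwhm(centers))
    if np.any(fwhm <= 0):
        raise ValueError("FWHM must be positive over the whole grid")
    sigma = fwhm / params.fwhm_factor

    min_sigma = 0.25 * float(np.min(r.grid.widths))
    kernel = np.zeros((r.grid.n_channels, r.grid.n_channels))
    for i in range(r.grid.n_channels):
        if sigma[i] < min_sigma:
            kernel[i, i] = 1.0
            continue
        k = np.exp(-0.5 * ((centers - centers[i]) / sigma[i]) ** 2)
        kernel[:, i] = k / k.sum()
    return ResponseMatrix(
        grid=r.grid,
        source_energies=r.source_energies,
        values=kernel @ r.values,
        condition=r.condition,
        broadened=True,
        geom=r.geom,
    )


def make_spectrum(
    r: ResponseMatrix,
    e0_keV: float,
    fluence_rate: float = 1.0,
    live_time_s: float = 1.0,
    noise: str = "none",
    seed: int | None = None,
) -> Spectrum:
    """Mono-energetic spectrum from one response column.

    Expected counts are ``column * fluence_rate * live_time``; with
    ``noise="poisson"`` each channel is drawn from a Poisson distribution
    with that expectation (seeded).  Provenance (true E0, fluence rate,
    condition) is stored in ``Spectrum.meta``.
    """
    if noise not in ("none", "poisson"):
        raise ValueError(f"unknown noise model {noise!r}")
    if fluence_rate < 0 or live_time_s <= 0:
        raise ValueError("fluence_rate must be >= 0 and live_time > 0")
    expected = r.column(e0_keV) * fluence_rate * live_time_s
    if noise == "poisson":
        rng = np.random.default_rng(seed)
        counts = rng.poisson(expected).astype(float)
    else:
        counts = expected
    return Spectrum(
        grid=r.grid,
        counts=counts,
        live_time_s=live_time_s,
        meta={
            "true_e0_keV": float(e0_keV),
            "fluence_rate_per_cm2_s": float(fluence_rate),
            "condition": r.condition.label,
            "noise": noise,
        },
    )
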