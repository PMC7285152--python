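"""Dose-rate estimation from spectra, and the energy-response diagnostic.

The point estimate is the discretised conversion sum

    D = sum_i M(E_i) G(E_i)

with M the channel count rates (1/s) and G in pSv per count, giving D in
pSv/s, reported in uSv/h.  Feeding the same spectrum through a set of
sampled G(E)GPR realizations instead yields a distribution of dose rates,
summarised by its mean, SD and the mean -/+ 1.96 SD interval.

The energy response compares estimate and truth across energy, normalised
at the Cs-137 reference energy of 662 keV:

    response(E0) = [est(E0) / true(E0)] / [est(662) / true(662)]
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .dose_coeffs import (
    PSV_PER_S_TO_USV_PER_H,
    ConversionCoefficientTable,
    interpolate_h,
)
from .spectrum import Spectrum

__all__ = [
    "DoseEstimate",
    "estimate_dose_point",
    "estimate_dose_distribution",
    "true_dose_rate",
    "energy_response",
]

logger = logging.getLogger(__name__)


@dataclass
class DoseEstimate:
    """Dose-rate distribution (uSv/h) from G(E)GPR realizations."""

    samples: np.ndarray
    mean: float
    sd: float
    ci_low: float
    ci_high: float
    n_realizations: int

    @property
    def relative_uncertainty(self) -> float:
        """(1.96 * SD) / mean — the expanded relative uncertainty."""
        return 1.96 * self.sd / self.mean if self.mean != 0 else np.inf

    def contains(self, value: float) -> bool:
        return self.ci_low <= value <= self.ci_high


def estimate_dose_point(spec: Spectrum, g_values: np.ndarray) -> float:
    """D = sum_i M(E_i) G(E_i), returned in uSv/h.

    ``g_values`` must be G evaluated on ``spec.grid`` channel centers
    (pSv per count).  Negative G values (possible in GP tails) are kept —
    clamping would bias the mean; a warning is logged if they are frequent.
    """
    g = np.asarray(g_values, dtype=float)
    if g.shape != (spec.grid.n_channels,):
        raise ValueError("G values must be given per channel of the spectrum grid")
    frac_neg = np.mean(g < 0)
    if frac_neg > 0.01:
        logger.warning("%.1f%% of G values are negative", 100 * frac_neg)
    return float(spec.count_rates @ g) * PSV_PER_S_TO_USV_PER_H


def estimate_dose_distribution(spec: Spectrum, realizations: np.ndarray) -> DoseEstimate:
    """Apply the conversion sum per realization and summarise.

    ``realizations`` has shape (n_realizations, n_channels) with
    n_realizations >= 2 (the SD is undefined otherwise).
    """
    reals = np.atleast_2d(np.asarray(realizations, dtype=float))
    if reals.shape[0] < 2:
        raise ValueError("need at least 2 realizations for a dose distribution")
    if reals.shape[1] != spec.grid.n_channels:
        raise ValueError("realizations must be defined on the spectrum grid")
    frac_neg = np.mean(reals < 0)
    if frac_neg > 0.01:
        logger.warning(
            "%.1f%% of realization-channel G values are negative", 100 * frac_neg
        )
    samples = (reals @ spec.count_rates) * PSV_PER_S_TO_USV_PER_H
    mean = float(np.mean(samples))
    sd = float(np.std(samples, ddof=1))
    return DoseEstimate(
        samples=samples,
        mean=mean,
        sd=sd,
        ci_low=mean - 1.96 * sd,
        ci_high=mean + 1.96 * sd,
        n_realizations=samples.size,
    )


def true_dose_rate(
    e0_keV: float, fluence_rate: float, table: ConversionCoefficientTable
) -> float:
    """Reference dose rate fluence_rate * h*(10)(E0), in uSv/h."""
    if fluence_rate < 0:
        raise ValueError("fluence rate must be non-negative")
    return fluence_rate * interpolate_h(table, e0_keV) * PSV_PER_S_TO_USV_PER_H


def energy_response(
    estimates: Mapping[float, float],
    truths: Mapping[float, float],
    ref_energy_keV: float = 662.0,
) -> dict[float, float]:
    """Estimated/true dose-rate ratio, normalised at ``ref_energy_keV``."""
    if ref_energy_keV not in estimates or ref_energy_keV not in truths:
        raise ValueError(f"reference energy {ref_energy_keV} keV missing from inputs")
    for e, t in truths.items():
        if t <= 0:
            raise ValueError(f"true dose rate at {e} keV must be positive")
    ref_ratio = estimates[ref_energy_keV] / truths[ref_energy_keV]
    return {
        e: (estimates[e] / truths[e]) / ref_ratio
        for e in estimates
        if e in truths
    }
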