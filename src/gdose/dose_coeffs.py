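"""Fluence-to-ambient-dose-equivalent conversion coefficients h*(10)(E0).

The packaged default table holds the ICRP Publication 74 / ICRU Report 57
coefficients (pSv cm^2 per unit fluence) for mono-energetic photons.  Any
two-column CSV (keV, pSv cm^2) can be supplied instead; the table is an
input to the G(E) fit, not a result of this package.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np

__all__ = [
    "ConversionCoefficientTable",
    "interpolate_h",
    "load_default_h_table",
    "read_h_table",
    "write_h_table",
    "PSV_PER_S_TO_USV_PER_H",
]

# 1 pSv/s = 3600 s/h * 1e-6 uSv/pSv = 3.6e-3 uSv/h
PSV_PER_S_TO_USV_PER_H = 3.6e-3


@dataclass
class ConversionCoefficientTable:
    """h*(10) per unit fluence (pSv cm^2) at strictly increasing energies (keV)."""

    energies_keV: np.ndarray
    coefficients_pSv_cm2: np.ndarray
    source_label: str = ""

    def __post_init__(self) -> None:
        self.energies_keV = np.asarray(self.energies_keV, dtype=float)
        self.coefficients_pSv_cm2 = np.asarray(self.coefficients_pSv_cm2, dtype=float)
        if self.energies_keV.ndim != 1 or self.energies_keV.size < 2:
            raise ValueError("need at least two table knots")
        if self.energies_keV.shape != self.coefficients_pSv_cm2.shape:
            raise ValueError("energies and coefficients must have equal length")
        if not np.all(np.diff(self.energies_keV) > 0):
            raise ValueError("table energies must be strictly increasing")
        if np.any(self.coefficients_pSv_cm2 <= 0):
            raise ValueError("conversion coefficients must be positive")

    @property
    def range_keV(self) -> tuple[float, float]:
        return float(self.energies_keV[0]), float(self.energies_keV[-1])


def interpolate_h(
    table: ConversionCoefficientTable, e0_keV: np.ndarray | float
) -> np.ndarray | float:
    """Log-log linear interpolation of h*(10); exact at knots, no extrapolation."""
    e = np.atleast_1d(np.asarray(e0_keV, dtype=float))
    lo, hi = table.range_keV
    if np.any(e < lo) or np.any(e > hi):
        raise ValueError(f"energy outside conversion table range [{lo:g}, {hi:g}] keV")
    out = np.exp(
        np.interp(
            np.log(e), np.log(table.energies_keV), np.log(table.coefficients_pSv_cm2)
        )
    )
    return out if np.ndim(e0_keV) else float(out[0])


def load_default_h_table() -> ConversionCoefficientTable:
    ref = resources.files("gdose.data") / "h10_conversion_coefficients.csv"
    raw = np.loadtxt(str(ref), delimiter=",", comments="#")
    return ConversionCoefficientTable(
        energies_keV=raw[:, 0],
        coefficients_pSv_cm2=raw[:, 1],
        source_label="ICRP 74 / ICRU 57 h*(10) per fluence",
    )


def read_h_table(path: str | Path) -> ConversionCoefficientTable:
    label = ""
    for line in Path(path).read_text().splitlines():
        if line.startswith("#"):
            label = line[1:].strip()
            break
    raw = np.loadtxt(str(path), delimiter=",", comments="#")
    return ConversionCoefficientTable(
        energies_keV=raw[:, 0], coefficients_pSv_cm2=raw[:, 1], source_label=label
    )


def write_h_table(table: ConversionCoefficientTable, path: str | Path) -> None:
    lines = [f"# {table.source_label}", "# columns: energy_keV, h10_pSv_cm2"]
    for e, h in zip(table.energies_keV, table.coefficients_pSv_cm2):
        lines.append(f"{float(e)!r},{float(h)!r}")
    Path(path).write_text("\n".join(lines) + "\n")
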