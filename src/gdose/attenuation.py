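"""Photon interaction coefficients for the scintillator material.

A small packaged table of mass interaction coefficients (photoelectric,
incoherent/Compton, pair production) for NaI is log-log interpolated.  The
table is an approximate smooth representation of the NIST XCOM database —
sufficient for the simplified transport model used here, and packaged so the
library needs no network access.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np

__all__ = ["InteractionTable", "load_nai_table"]

_PAIR_THRESHOLD_KEV = 1022.0


@dataclass
class InteractionTable:
    """Mass interaction coefficients (cm^2/g) on an energy knot grid (keV)."""

    energies_keV: np.ndarray
    tau_photo: np.ndarray
    sigma_incoherent: np.ndarray
    kappa_pair: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        for name in ("energies_keV", "tau_photo", "sigma_incoherent", "kappa_pair"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if not np.all(np.diff(self.energies_keV) > 0):
            raise ValueError("table energies must be strictly increasing")

    def _check_range(self, e: np.ndarray) -> None:
        if np.any(e < self.energies_keV[0]) or np.any(e > self.energies_keV[-1]):
            raise ValueError(
                f"energy outside interaction table range "
                f"[{self.energies_keV[0]:g}, {self.energies_keV[-1]:g}] keV"
            )

    def _loglog(self, values: np.ndarray, e: np.ndarray) -> np.ndarray:
        # log-log interpolation over strictly positive knots only
        pos = values > 0
        out = np.zeros_like(e, dtype=float)
        if pos.sum() >= 2:
            lo = self.energies_keV[pos][0]
            sel = e >= lo
            out[sel] = np.exp(
                np.interp(
                    np.log(e[sel]),
                    np.log(self.energies_keV[pos]),
                    np.log(values[pos]),
                )
            )
        return out

    def mu_rho(self, energy_keV: np.ndarray | float, process: str = "total") -> np.ndarray | float:
        """Mass interaction coefficient (cm^2/g) at ``energy_keV``.

        ``process`` is one of ``photo``, ``incoherent``, ``pair``, ``total``.
        Pair production is clamped to zero below the 1022 keV threshold.
        """
        e = np.atleast_1d(np.asarray(energy_keV, dtype=float))
        self._check_range(e)
        if process == "photo":
            out = self._loglog(self.tau_photo, e)
        elif process == "incoherent":
            out = self._loglog(self.sigma_incoherent, e)
        elif process == "pair":
            out = self._loglog(self.kappa_pair, e)
            out[e < _PAIR_THRESHOLD_KEV] = 0.0
        elif process == "total":
            out = (
                self.mu_rho(e, "photo")
                + self.mu_rho(e, "incoherent")
                + self.mu_rho(e, "pair")
            )
        else:
            raise ValueError(f"unknown process {process!r}")
        return out if np.ndim(energy_keV) else float(out[0])


def load_nai_table() -> InteractionTable:
    """Packaged NaI interaction coefficient table (40-4000 keV)."""
    ref = resources.files("gdose.data") / "nai_interaction_coefficients.csv"
    raw = np.loadtxt(str(ref), delimiter=",", comments="#")
    return InteractionTable(
        energies_keV=raw[:, 0],
        tau_photo=raw[:, 1],
        sigma_incoherent=raw[:, 2],
        kappa_pair=raw[:, 3],
        label="NaI (approximate XCOM representation)",
    )
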