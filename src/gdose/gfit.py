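"""The spectrum-to-dose conversion operator G(E) and its calibration.

G(E) is a polynomial in the logarithm of the deposited energy,

    G(E) = sum_{K=1}^{Kmax} A(K) * (log10 E)^(K - M - 1),

with Kmax = 7 and M = 0 by default.  Its defining property is that the
detector response folds it back onto the fluence-to-dose conversion
coefficient at every calibration energy:

    h(E0_j) = sum_i R[i, j] * G(E_i)        (channel-center quadrature)

The coefficients A are obtained by gradient descent on the mean squared
*relative* error of the predicted coefficients, so that keV-range and
MeV-range energies (whose h differ by an order of magnitude) contribute
comparably.  The log-energy power basis is severely ill-conditioned, so the
descent runs in a QR-orthonormalised (whitened) coordinate system; the
reported A are mapped back exactly and reproduce the fitted function
identically in the raw basis.

Below a configurable support threshold G is taken to be zero: the
polynomial has no data there and its extrapolation is meaningless.  The
default threshold sits a factor of two below the lowest calibration energy
(25 keV for the standard 50-3000 keV calibration) so that the broadened
full-energy peak of the lowest calibration column is not truncated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .detector import EnergyGrid
from .dose_coeffs import ConversionCoefficientTable, interpolate_h
from .response import ResponseMatrix

__all__ = [
    "GFunctionParams",
    "FitReport",
    "FitOptions",
    "evaluate_g",
    "g_on_grid",
    "predicted_dose_coefficients",
    "fit_g",
]


@dataclass
class GFunctionParams:
    """Coefficient vector A defining one G(E) function (pSv per count)."""

    coefficients: np.ndarray
    m_offset: int = 0
    log_base: str = "10"  # "10" or "e"
    energy_unit: str = "keV"
    geometry_label: str = ""
    support_keV: tuple[float, float] | None = (50.0, 3100.0)

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.coefficients.ndim != 1 or self.coefficients.size < 1:
            raise ValueError("need at least one coefficient (Kmax >= 1)")
        if self.log_base not in ("10", "e"):
            raise ValueError("log_base must be '10' or 'e'")

    @property
    def kmax(self) -> int:
        return self.coefficients.size


def _log_energy(energies: np.ndarray, log_base: str) -> np.ndarray:
    e = np.asarray(energies, dtype=float)
    if np.any(e <= 1.0):
        raise ValueError("G(E) basis requires energies > 1 keV")
    return np.log10(e) if log_base == "10" else np.log(e)


def basis_matrix(
    energies: np.ndarray, kmax: int, m_offset: int = 0, log_base: str = "10"
) -> np.ndarray:
    """Columns (log E)^(K - M - 1) for K = 1..Kmax; shape (n_energies, kmax)."""
    x = _log_energy(energies, log_base)
    powers = np.arange(1, kmax + 1) - m_offset - 1
    return x[:, None] ** powers[None, :]


def evaluate_g(params: GFunctionParams, energies: np.ndarray | float) -> np.ndarray | float:
    """G(E) at the given energies (keV), ignoring the support window."""
    e = np.atleast_1d(np.asarray(energies, dtype=float))
    b = basis_matrix(e, params.kmax, params.m_offset, params.log_base)
    out = b @ params.coefficients
    return out if np.ndim(energies) else float(out[0])


def g_on_grid(params: GFunctionParams, grid: EnergyGrid) -> np.ndarray:
    """G evaluated on channel centers, zeroed outside the support window."""
    centers = grid.centers
    g = np.zeros(grid.n_channels)
    if params.support_keV is None:
        mask = centers > 1.0
    else:
        lo, hi = params.support_keV
        mask = (centers >= lo) & (centers <= hi)
    g[mask] = evaluate_g(params, centers[mask])
    return g


def predicted_dose_coefficients(r: ResponseMatrix, params: GFunctionParams) -> np.ndarray:
    """h_pred(E0_j) = sum_i R[i,j] G(E_i) for every source energy of ``r``."""
    if not r.broadened:
        raise ValueError("dose coefficients are defined on the broadened response")
    return r.values.T @ g_on_grid(params, r.grid)


@dataclass
class FitOptions:
    kmax: int = 7
    m_offset: int = 0
    log_base: str = "10"
    support_keV: tuple[float, float] | None = None  # default: [min calib, grid top]
    max_iter: int = 100_000
    rel_tol: float = 1e-10
    step0: float = 1.0


@dataclass
class FitReport:
    final_loss: float
    residuals: np.ndarray  # h_pred/h_true - 1 at calibration energies
    n_iterations: int
    converged: bool
    loss_history: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def rms_relative_error(self) -> float:
        return float(np.sqrt(np.mean(self.residuals**2)))


def fit_g(
    r: ResponseMatrix,
    table: ConversionCoefficientTable,
    calibration_energies: np.ndarray,
    opts: FitOptions | None = None,
) -> tuple[GFunctionParams, FitReport]:
    """Calibrate G(E) against ``table`` through the response matrix ``r``.

    Minimises ``mean_j (h_pred(E0_j)/h(E0_j) - 1)^2`` by gradient descent
    with backtracking step halving, starting from A = 0.  Deterministic and
    seed-free.  Raises if there are fewer calibration energies than basis
    terms; non-convergence within ``max_iter`` is reported, not raised.
    """
    opts = opts or FitOptions()
    calib = np.asarray(calibration_energies, dtype=float)
    if calib.size < opts.kmax:
        raise ValueError(
            f"need at least Kmax={opts.kmax} calibration energies, got {calib.size}"
        )
    lo, hi = table.range_keV
    if np.any(calib < lo) or np.any(calib > hi):
        raise ValueError("calibration energies outside conversion table range")
    cols = [r.column_index(e) for e in calib]

    # the default support reaches a factor of two below the lowest
    # calibration energy so that the broadened full-energy peak of that
    # column is not truncated by the zero-G threshold
    support = opts.support_keV or (0.5 * float(calib.min()), float(r.grid.edges[-1]))
    centers = r.grid.centers
    mask = (centers >= support[0]) & (centers <= support[1])
    basis = np.zeros((r.grid.n_channels, opts.kmax))
    basis[mask] = basis_matrix(centers[mask], opts.kmax, opts.m_offset, opts.log_base)

    h_true = interpolate_h(table, calib)
    design = (r.values[:, cols].T @ basis) / h_true[:, None]  # (n_calib, kmax)

    # whiten: descend in an orthonormal basis, map the solution back exactly
    q, r_fac = np.linalg.qr(design)
    n = calib.size
    target = np.ones(n)

    w = np.zeros(opts.kmax)
    resid = q @ w - target
    loss = float(resid @ resid) / n
    history = [loss]
    step = opts.step0
    converged = False
    it = 0
    for it in range(1, opts.max_iter + 1):
        grad = 2.0 / n * (q.T @ resid)
        gnorm2 = float(grad @ grad)
        if gnorm2 == 0.0:
            converged = True
            break
        # backtracking: halve the step until the loss decreases
        while True:
            w_new = w - step * grad
            resid_new = q @ w_new - target
            loss_new = float(resid_new @ resid_new) / n
            if loss_new < loss or step < 1e-20:
                break
            step *= 0.5
        if loss_new >= loss:
            # no decrease possible: at (numerical) optimality when the loss
            # or gradient has reached floating-point scale
            converged = loss <= 1e-18 or gnorm2 <= 1e-24
            break
        w, resid = w_new, resid_new
        rel_change = (loss - loss_new) / max(loss, 1e-300)
        loss = loss_new
        history.append(loss)
        step = min(step * 2.0, opts.step0)
        if rel_change < opts.rel_tol:
            converged = True
            break

    coeffs = np.linalg.solve(r_fac, w)
    params = GFunctionParams(
        coefficients=coeffs,
        m_offset=opts.m_offset,
        log_base=opts.log_base,
        geometry_label=r.condition.label,
        support_keV=support,
    )
    h_pred = (design @ coeffs) * h_true
    report = FitReport(
        final_loss=loss,
        residuals=h_pred / h_true - 1.0,
        n_iterations=it,
        converged=converged,
        loss_history=np.asarray(history),
    )
    return params, report
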