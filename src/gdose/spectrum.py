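"""Pulse-height spectra: container plus CSV and IAEA SPE ASCII readers."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .detector import EnergyGrid

__all__ = ["Spectrum", "read_spectrum_csv", "write_spectrum_csv", "read_spe"]


@dataclass
class Spectrum:
    """Channel counts acquired over ``live_time_s`` on an energy grid.

    ``meta`` optionally carries provenance for simulated spectra: the true
    incident energy (keV), fluence rate (1/cm^2/s) and irradiation geometry.
    """

    grid: EnergyGrid
    counts: np.ndarray
    live_time_s: float = 1.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (self.grid.n_channels,):
            raise ValueError("counts length must equal the number of channels")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if self.live_time_s <= 0:
            raise ValueError("live time must be positive")

    @property
    def count_rates(self) -> np.ndarray:
        """M(Ei): counts per second per channel."""
        return self.counts / self.live_time_s


def write_spectrum_csv(spec: Spectrum, path: str | Path) -> None:
    path = Path(path)
    lines = ["# gdose spectrum", f"# live_time_s: {float(spec.live_time_s)!r}"]
    for k, v in sorted(spec.meta.items()):
        v = float(v) if isinstance(v, (int, float)) and not isinstance(v, bool) else v
        lines.append(f"# meta {k}: {v!r}")
    lines.append(f"# edge0_keV: {float(spec.grid.edges[0])!r}")
    lines.append("# columns: energy_keV(center),counts,upper_edge_keV")
    for e_hi, center, c in zip(spec.grid.edges[1:], spec.grid.centers, spec.counts):
        lines.append(f"{float(center)!r},{float(c)!r},{float(e_hi)!r}")
    path.write_text("\n".join(lines) + "\n")


def read_spectrum_csv(path: str | Path) -> Spectrum:
    path = Path(path)
    live_time = 1.0
    meta: dict = {}
    edge0 = None
    centers, counts, hi_edges = [], [], []
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line[1:].strip()
            if body.startswith("live_time_s:"):
                live_time = float(body.split(":", 1)[1])
            elif body.startswith("edge0_keV:"):
                edge0 = float(body.split(":", 1)[1])
            elif body.startswith("meta "):
                k, v = body[5:].split(":", 1)
                meta[k.strip()] = eval(v.strip(), {"__builtins__": {}})  # noqa: S307 - own format
            continue
        parts = line.split(",")
        centers.append(float(parts[0]))
        counts.append(float(parts[1]))
        if len(parts) > 2:
            hi_edges.append(float(parts[2]))
    if edge0 is None or len(hi_edges) != len(centers):
        raise ValueError(f"{path} is not a gdose spectrum CSV")
    grid = EnergyGrid(np.concatenate([[edge0], hi_edges]))
    return Spectrum(grid=grid, counts=np.array(counts), live_time_s=live_time, meta=meta)


def read_spe(path: str | Path) -> Spectrum:
    """Read an IAEA SPE ASCII spectrum ($DATA block, $ENER_FIT calibration).

    The energy calibration ``E = b0 + b1*ch`` from $ENER_FIT (or $MCA_CAL)
    is applied to channel boundaries to build the energy grid; $MEAS_TIM
    supplies the live time when present.
    """
    text = Path(path).read_text()
    blocks: dict[str, list[str]] = {}
    current = None
    for line in text.splitlines():
        if line.startswith("$"):
            current = line.strip().rstrip(":")
            blocks[current] = []
        elif current is not None:
            blocks[current].append(line.strip())
    if "$DATA" not in blocks:
        raise ValueError("SPE file has no $DATA block")
    data_lines = [ln for ln in blocks["$DATA"] if ln]
    first, last = (int(t) for t in data_lines[0].split())
    counts = np.array(
        [float(tok) for ln in data_lines[1:] for tok in ln.split()], dtype=float
    )
    n = last - first + 1
    if counts.size < n:
        raise ValueError("SPE $DATA block shorter than declared channel range")
    counts = counts[:n]

    b0, b1 = 0.0, 1.0
    for key in ("$ENER_FIT", "$MCA_CAL"):
        if key in blocks:
            toks: list[float] = []
            for ln in blocks[key]:
                for t in ln.split():
                    try:
                        toks.append(float(t))
                    except ValueError:
                        pass
            if len(toks) >= 2:
                b0, b1 = toks[0], toks[1]
                break
    if b1 <= 0:
        raise ValueError("SPE energy calibration gain must be positive")
    ch_edges = np.arange(first, last + 2) - 0.5
    grid = EnergyGrid(b0 + b1 * ch_edges)

    live_time = 1.0
    if "$MEAS_TIM" in blocks:
        toks = blocks["$MEAS_TIM"][0].split()
        if toks:
            live_time = float(toks[0])
    return Spectrum(grid=grid, counts=counts, live_time_s=live_time, meta={"source": str(path)})
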