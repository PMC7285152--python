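"""Readers and writers for response matrices, G functions and GP models.

All formats are plain text (CSV / JSON).  Floats are written with ``repr``
precision so every reader/writer pair round-trips bit-exactly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .detector import DetectorGeometry, EnergyGrid, GeometryCondition
from .gfit import GFunctionParams
from .gp import GPHyperparams, GPPosterior, GPTrainingSet
from .response import ResponseMatrix

__all__ = [
    "write_response_csv",
    "read_response_csv",
    "write_gfunction_json",
    "read_gfunction_json",
    "write_gp_json",
    "read_gp_json",
]

def _r(x: float) -> str:
    """repr of a python float: shortest round-trippable decimal text."""
    return repr(float(x))


def write_response_csv(r: ResponseMatrix, path: str | Path) -> None:
    """Header row of source energies, first column of channel centers."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("# gdose response matrix\n")
        fh.write("# units: cm^2\n")
        fh.write(f"# condition: {r.condition.mode}")
        if r.condition.angle_deg is not None:
            fh.write(f" {_r(r.condition.angle_deg)}")
        fh.write("\n")
        fh.write(f"# broadened: {r.broadened}\n")
        fh.write(
            f"# geometry: {_r(r.geom.diameter_cm)} {_r(r.geom.height_cm)} "
            f"{_r(r.geom.density_g_cm3)}\n"
        )
        fh.write("# edges: " + ",".join(_r(e) for e in r.grid.edges) + "\n")
        fh.write("E_keV," + ",".join(_r(e) for e in r.source_energies) + "\n")
        for center, row in zip(r.grid.centers, r.values):
            fh.write(_r(center) + "," + ",".join(_r(v) for v in row) + "\n")


def read_response_csv(path: str | Path) -> ResponseMatrix:
    path = Path(path)
    condition = GeometryCondition.at_angle(0.0)
    broadened = False
    geom = DetectorGeometry()
    edges = None
    source_energies = None
    rows = []
    for line in path.read_text().splitlines():
        if not line.strip():
            continue
        if line.startswith("#"):
            body = line[1:].strip()
            if body.startswith("condition:"):
                toks = body.split(":", 1)[1].split()
                if toks[0] == "isotropic":
                    condition = GeometryCondition.isotropic()
                else:
                    condition = GeometryCondition.at_angle(float(toks[1]))
            elif body.startswith("broadened:"):
                broadened = body.split(":", 1)[1].strip() == "True"
            elif body.startswith("geometry:"):
                d, h, rho = (float(t) for t in body.split(":", 1)[1].split())
                geom = DetectorGeometry(diameter_cm=d, height_cm=h, density_g_cm3=rho)
            elif body.startswith("edges:"):
                edges = np.array([float(t) for t in body.split(":", 1)[1].split(",")])
            continue
        toks = line.split(",")
        if toks[0] == "E_keV":
            source_energies = np.array([float(t) for t in toks[1:]])
        else:
            rows.append([float(t) for t in toks[1:]])
    if edges is None or source_energies is None:
        raise ValueError(f"{path} is not a gdose response matrix CSV")
    return ResponseMatrix(
        grid=EnergyGrid(edges),
        source_energies=source_energies,
        values=np.array(rows),
        condition=condition,
        broadened=broadened,
        geom=geom,
    )


def write_gfunction_json(
    params: GFunctionParams, path: str | Path, fit_meta: dict | None = None
) -> None:
    doc = {
        "coefficients": list(params.coefficients),
        "m_offset": params.m_offset,
        "log_base": params.log_base,
        "energy_unit": params.energy_unit,
        "geometry_label": params.geometry_label,
        "support_keV": list(params.support_keV) if params.support_keV else None,
        "fit": fit_meta or {},
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def read_gfunction_json(path: str | Path) -> GFunctionParams:
    doc = json.loads(Path(path).read_text())
    return GFunctionParams(
        coefficients=np.array(doc["coefficients"]),
        m_offset=doc["m_offset"],
        log_base=doc["log_base"],
        energy_unit=doc.get("energy_unit", "keV"),
        geometry_label=doc.get("geometry_label", ""),
        support_keV=tuple(doc["support_keV"]) if doc.get("support_keV") else None,
    )


def write_gp_json(
    post: GPPosterior, train: GPTrainingSet, path: str | Path, meta: dict | None = None
) -> None:
    doc = {
        "hyperparams": {
            "lengthscale": post.hyper.lengthscale,
            "signal_var": post.hyper.signal_var,
            "noise_var": post.hyper.noise_var,
            "jitter": post.hyper.jitter,
        },
        "y_mean": post.y_mean,
        "y_scale": post.y_scale,
        "train_x": list(train.x),
        "train_y": list(train.y),
        "train_tags": list(map(str, train.tags)) if train.tags is not None else None,
        "meta": meta or {},
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def read_gp_json(path: str | Path) -> tuple[GPTrainingSet, GPHyperparams]:
    doc = json.loads(Path(path).read_text())
    hp = doc["hyperparams"]
    train = GPTrainingSet(
        x=np.array(doc["train_x"]),
        y=np.array(doc["train_y"]),
        tags=np.array(doc["train_tags"]) if doc.get("train_tags") else None,
    )
    hyper = GPHyperparams(
        lengthscale=hp["lengthscale"],
        signal_var=hp["signal_var"],
        noise_var=hp["noise_var"],
        jitter=hp.get("jitter", 1e-10),
    )
    return train, hyper
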