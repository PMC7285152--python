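"""End-to-end orchestration: responses -> G(E) fits -> GP -> validation.

The pipeline reproduces the full study design on the built-in simplified
simulator:

1. simulate broadened response matrices for each irradiation condition
   (default 0, 45, 90 degrees and isotropic);
2. fit one G(E) function per condition against the h*(10) table;
3. pool the fitted functions into a GP training set over log10 energy and
   fit kernel hyperparameters by marginal likelihood;
4. draw G(E)GPR realizations from the posterior;
5. validate: for mono-energetic test spectra under every condition,
   compare the 0-degree point estimate and the GP dose distribution with
   the fluence x h*(10) truth, as energy responses normalised at 662 keV.

Every stochastic stage takes its seed from the single configured seed, so
a rerun with the same configuration is identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import tomllib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import gp as gpmod
from .detector import BroadeningParams, DetectorGeometry, EnergyGrid, GeometryCondition
from .dose_coeffs import ConversionCoefficientTable, load_default_h_table, read_h_table
from .estimator import (
    energy_response,
    estimate_dose_distribution,
    estimate_dose_point,
    true_dose_rate,
)
from .gfit import FitOptions, FitReport, GFunctionParams, fit_g, g_on_grid
from .io import write_gfunction_json, write_gp_json, write_response_csv
from .response import (
    PhysicsModel,
    ResponseMatrix,
    apply_broadening,
    isotropic_response,
    make_spectrum,
    simulate_response,
)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "build_training_set"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    # detector and grid
    diameter_cm: float = 5.08
    height_cm: float = 5.08
    density_g_cm3: float = 3.6
    n_channels: int = 869
    grid_min_keV: float = 0.0
    grid_max_keV: float = 3100.0
    # broadening
    broaden_a: float = 1.0
    broaden_b: float = 1.8
    broaden_c: float = 0.0
    fwhm_factor: float = 2.36
    # irradiation conditions
    angles_deg: tuple[float, ...] = (0.0, 45.0, 90.0)
    include_isotropic: bool = True
    n_iso_angles: int = 16
    # calibration and test energies (keV)
    n_calibration: int = 30
    calib_min_keV: float = 50.0
    calib_max_keV: float = 3000.0
    n_test: int = 20
    ref_energy_keV: float = 662.0
    # G(E) fit
    kmax: int = 7
    m_offset: int = 0
    log_base: str = "10"
    # GP
    gp_stride: int = 8
    n_samples: int = 100
    realization_noise: str = "correlated"
    gp_n_starts: int = 8
    # inputs / outputs
    h_table_path: str | None = None
    fluence_rate: float = 1.0
    live_time_s: float = 1.0
    seed: int | None = None
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("pipeline configuration requires an explicit seed")
        if not self.angles_deg and not self.include_isotropic:
            raise ValueError("at least one irradiation condition is required")
        if self.realization_noise not in ("none", "iid", "correlated"):
            raise ValueError(f"unknown realization_noise {self.realization_noise!r}")
        if self.calib_min_keV <= 1.0 or self.calib_max_keV > self.grid_max_keV:
            raise ValueError("calibration range must lie in (1 keV, grid top]")

    @classmethod
    def from_toml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, "rb") as fh:
            doc = tomllib.load(fh)
        flat: dict = {}
        for key, val in doc.items():
            if isinstance(val, dict):
                flat.update(val)
            else:
                flat[key] = val
        if "angles_deg" in flat:
            flat["angles_deg"] = tuple(float(a) for a in flat["angles_deg"])
        return cls(**flat)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def calibration_energies(self) -> np.ndarray:
        return np.geomspace(self.calib_min_keV, self.calib_max_keV, self.n_calibration)

    def test_energies(self) -> np.ndarray:
        e = np.geomspace(self.calib_min_keV, self.calib_max_keV, self.n_test)
        return np.unique(np.append(e, self.ref_energy_keV))

    def detector(self) -> DetectorGeometry:
        return DetectorGeometry(
            diameter_cm=self.diameter_cm,
            height_cm=self.height_cm,
            density_g_cm3=self.density_g_cm3,
        )

    def grid(self) -> EnergyGrid:
        return EnergyGrid.linear(self.n_channels, self.grid_min_keV, self.grid_max_keV)

    def broadening(self) -> BroadeningParams:
        return BroadeningParams(
            a=self.broaden_a, b=self.broaden_b, c=self.broaden_c,
            fwhm_factor=self.fwhm_factor,
        )

    def h_table(self) -> ConversionCoefficientTable:
        if self.h_table_path:
            return read_h_table(self.h_table_path)
        return load_default_h_table()

    def conditions(self) -> list[GeometryCondition]:
        conds = [GeometryCondition.at_angle(a) for a in self.angles_deg]
        if self.include_isotropic:
            conds.append(GeometryCondition.isotropic())
        return conds


@dataclass
class PipelineResult:
    config: PipelineConfig
    responses: dict[str, ResponseMatrix]
    gfunctions: dict[str, GFunctionParams]
    fit_reports: dict[str, FitReport]
    train: gpmod.GPTrainingSet
    hyper: gpmod.GPHyperparams
    posterior: gpmod.GPPosterior
    realizations: np.ndarray  # (n_samples, n_channels), zero outside support
    validation: pd.DataFrame
    summary: dict = field(default_factory=dict)


def build_training_set(
    gfunctions: dict[str, GFunctionParams],
    grid: EnergyGrid,
    stride: int = 8,
    lo_keV: float = 50.0,
    hi_keV: float = 3000.0,
) -> gpmod.GPTrainingSet:
    """Pool every ``stride``-th channel of each geometry's G(E) function."""
    centers = grid.centers
    sel = np.nonzero((centers >= lo_keV) & (centers <= hi_keV))[0][::stride]
    xs, ys, tags = [], [], []
    for label, params in gfunctions.items():
        g = g_on_grid(params, grid)
        xs.append(np.log10(centers[sel]))
        ys.append(g[sel])
        tags.extend([label] * sel.size)
    return gpmod.GPTrainingSet(
        x=np.concatenate(xs), y=np.concatenate(ys), tags=np.array(tags)
    )


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    t0 = time.perf_counter()
    geom = config.detector()
    grid = config.grid()
    broaden = config.broadening()
    table = config.h_table()
    physics = PhysicsModel()
    calib = config.calibration_energies()
    test = config.test_energies()
    energies = np.unique(np.concatenate([calib, test]))
    out = Path(config.output_dir) if config.output_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)
    stamp = {"config_hash": config.config_hash(), "seed": config.seed}

    # stage 1: response matrices
    responses: dict[str, ResponseMatrix] = {}
    for cond in config.conditions():
        if cond.mode == "isotropic":
            raw = isotropic_response(geom, energies, grid, physics, config.n_iso_angles)
        else:
            raw = simulate_response(geom, cond, energies, grid, physics)
        responses[cond.label] = apply_broadening(raw, broaden)
        if out:
            write_response_csv(responses[cond.label], out / f"response_{cond.label}.csv")
    logger.info("responses simulated in %.1f s", time.perf_counter() - t0)

    # stage 2: G(E) per geometry
    support = (0.5 * config.calib_min_keV, float(grid.edges[-1]))
    opts = FitOptions(
        kmax=config.kmax, m_offset=config.m_offset, log_base=config.log_base,
        support_keV=support,
    )
    gfunctions: dict[str, GFunctionParams] = {}
    reports: dict[str, FitReport] = {}
    for label, resp in responses.items():
        params, report = fit_g(resp, table, calib, opts)
        gfunctions[label] = params
        reports[label] = report
        logger.info(
            "G(E) fit %s: rms rel err %.2e after %d iters",
            label, report.rms_relative_error, report.n_iterations,
        )
        if out:
            write_gfunction_json(
                params, out / f"g_{label}.json",
                fit_meta={**stamp, "rms_relative_error": report.rms_relative_error},
            )

    # stage 3: GP over pooled G data
    # the GP trains over the full support of the fitted G functions so that
    # realizations and point estimates weight the same channels
    train = build_training_set(
        gfunctions, grid, config.gp_stride, support[0], config.calib_max_keV
    )
    hyper = gpmod.fit_hyperparams(train, seed=config.seed, n_starts=config.gp_n_starts)
    logger.info(
        "GP hyperparameters: l=%.3f sf2=%.3g se2=%.3g (lml=%.1f)",
        hyper.lengthscale, hyper.signal_var, hyper.noise_var,
        gpmod.log_marginal_likelihood(train, hyper),
    )
    centers = grid.centers
    support_idx = np.nonzero((centers >= support[0]) & (centers <= support[1]))[0]
    post = gpmod.posterior(train, hyper, np.log10(centers[support_idx]))

    # stage 4: realizations on the full grid (zero outside support)
    reals_q = gpmod.sample_realizations(
        post, config.n_samples, seed=config.seed + 1, noise=config.realization_noise
    )
    realizations = np.zeros((config.n_samples, grid.n_channels))
    realizations[:, support_idx] = reals_q
    if out:
        write_gp_json(post, train, out / "gp_model.json", meta=stamp)
        np.savetxt(
            out / "g_realizations.csv",
            realizations.T,
            delimiter=",",
            fmt="%.17g",
            header="rows: channels, cols: realizations; " + json.dumps(stamp),
        )

    # stage 5: validation across test energies and geometries
    # the conservative reference function is the first configured condition
    # (0 degrees in the default study design)
    g0_label = next(iter(gfunctions))
    g0 = g_on_grid(gfunctions[g0_label], grid)
    gp_mean_full = np.zeros(grid.n_channels)
    gp_mean_full[support_idx] = post.mean
    rows = []
    for label, resp in responses.items():
        est_g0, est_mean, truth, dists = {}, {}, {}, {}
        for e0 in test:
            spec = make_spectrum(
                resp, e0, config.fluence_rate, config.live_time_s, noise="none"
            )
            truth[e0] = true_dose_rate(e0, config.fluence_rate, table)
            est_g0[e0] = estimate_dose_point(spec, g0)
            dists[e0] = estimate_dose_distribution(spec, realizations)
            est_mean[e0] = dists[e0].mean
        resp_g0 = energy_response(est_g0, truth, config.ref_energy_keV)
        resp_mean = energy_response(est_mean, truth, config.ref_energy_keV)
        ref_ratio = est_mean[config.ref_energy_keV] / truth[config.ref_energy_keV]
        for e0 in test:
            d = dists[e0]
            rows.append({
                "geometry": label,
                "E0_keV": e0,
                "true_uSv_h": truth[e0],
                "est_g0_uSv_h": est_g0[e0],
                "est_mean_uSv_h": est_mean[e0],
                "sd_uSv_h": d.sd,
                "ci_low_uSv_h": d.ci_low,
                "ci_high_uSv_h": d.ci_high,
                "response_g0": resp_g0[e0],
                "response_mean": resp_mean[e0],
                "response_lo": (d.ci_low / truth[e0]) / ref_ratio,
                "response_hi": (d.ci_high / truth[e0]) / ref_ratio,
                "rel_uncertainty": d.relative_uncertainty,
                "covers_true": d.contains(truth[e0]),
                "covers_g0": d.contains(est_g0[e0]),
            })
    validation = pd.DataFrame(rows)

    summary = {
        **stamp,
        "hyperparams": {
            "lengthscale": hyper.lengthscale,
            "signal_var": hyper.signal_var,
            "noise_var": hyper.noise_var,
        },
        "fit_rms_relative_error": {
            k: rep.rms_relative_error for k, rep in reports.items()
        },
        "coverage_true": float(validation["covers_true"].mean()),
        "coverage_g0": float(validation["covers_g0"].mean()),
        "coverage_both": float(
            (validation["covers_true"] & validation["covers_g0"]).mean()
        ),
        "runtime_s": time.perf_counter() - t0,
    }
    if out:
        validation.to_csv(out / "validation.csv", index=False, float_format="%.17g")
        (out / "summary.json").write_text(json.dumps(summary, indent=1))
    logger.info("pipeline finished in %.1f s", summary["runtime_s"])
    return PipelineResult(
        config=config,
        responses=responses,
        gfunctions=gfunctions,
        fit_reports=reports,
        train=train,
        hyper=hyper,
        posterior=post,
        realizations=realizations,
        validation=validation,
        summary=summary,
    )
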