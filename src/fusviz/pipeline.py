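"""End-to-end pipeline: simulate -> beamform -> reconstruct -> normalize ->
overlay -> metrics.  The CLI is a thin wrapper around these functions."""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Optional

import numpy as np

from . import io
from .config import RunConfig, config_hash
from .metrics import (
    MetricsReport,
    measure_width,
    theoretical_beamwidth,
    theoretical_dof,
)
from .reconstruct import BeamReconstruction, reconstruct_acquisition
from .scene import build_scene
from .simulate import AcquisitionResult, simulate_acquisition

__all__ = ["run_simulation", "run_reconstruction", "beam_metrics", "run_demo"]


def run_simulation(cfg: RunConfig) -> AcquisitionResult:
    """Build the configured scene and run the full excitation sequence."""
    scene = build_scene(cfg.scene, cfg.seed)
    return simulate_acquisition(cfg.array, scene, cfg.recon, seed=cfg.seed)


def run_reconstruction(acq: AcquisitionResult) -> BeamReconstruction:
    return reconstruct_acquisition(acq)


def beam_metrics(
    recon: BeamReconstruction,
    tx_f_number: float,
    level_db: float = -6.0,
    use_cf: bool = True,
    normalized: bool = False,
) -> MetricsReport:
    """Measure beamwidth / depth of field from a reconstruction and pair
    them with the theoretical continuous-wave values.

    ``tx_f_number`` is the transmit f-number (focal depth / aperture).
    Width measurements can fail on speckle-degraded profiles; failures are
    reported as ``None`` rather than raised.
    """
    beam = recon.beam_db(use_cf=use_cf, normalized=normalized)
    wl = recon.wavelength
    iz, ix = np.unravel_index(np.argmax(beam.values), beam.values.shape)
    bw = dof = None
    try:
        bw = measure_width(beam.values[iz, :], beam.x_grid, level_db) * 1e3
    except ValueError:
        pass
    try:
        dof = measure_width(beam.values[:, ix], beam.z_grid, level_db) * 1e3
    except ValueError:
        pass
    return MetricsReport(
        wavelength_mm=wl * 1e3,
        f_number=tx_f_number,
        theoretical_beamwidth_mm=theoretical_beamwidth(wl * 1e3, tx_f_number),
        theoretical_dof_mm=theoretical_dof(wl * 1e3, tx_f_number),
        level_db=level_db,
        beamwidth_mm=bw,
        dof_mm=dof,
    )


def run_demo(cfg: RunConfig, out_dir, verbose: bool = False) -> dict:
    """Full demo: simulate, reconstruct, write images/overlay/metrics.

    Returns a dict of output paths plus the metrics report.  Every artifact
    carries the config hash and seed so identical configs reproduce
    bit-identical outputs.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    digest = config_hash(cfg)
    stamp = {"config_hash": digest, "seed": cfg.seed}

    acq = run_simulation(cfg)
    rf_path = out / "rf_frames.h5"
    io.save_frames(rf_path, acq.frames, cfg.array, meta={**stamp, "sequence_log": acq.log})

    recon = run_reconstruction(acq)
    paths = {"rf": rf_path}
    for name, img in {
        "bmode_db": recon.bmode_db(),
        "intensity": recon.intensity(use_cf=cfg.recon.use_cf, normalized=False),
        "intensity_norm": recon.intensity(use_cf=cfg.recon.use_cf, normalized=True),
        "beam_db": recon.beam_db(use_cf=cfg.recon.use_cf),
    }.items():
        p = out / f"{name}.npz"
        io.save_image(p, img, **stamp)
        paths[name] = p

    overlay_path = out / "overlay.png"
    recon.overlay(path=overlay_path)
    paths["overlay"] = overlay_path

    fx, fz = cfg.recon.focus
    tx_f_number = fz / cfg.array.aperture
    report = beam_metrics(recon, tx_f_number, use_cf=cfg.recon.use_cf)
    report_path = out / "metrics.json"
    report.to_json(report_path)
    paths["metrics"] = report_path

    params_path = out / "params.json"
    with open(params_path, "w") as fh:
        json.dump({**stamp, "config": _cfg_dict(cfg)}, fh, indent=2, sort_keys=True)
    paths["params"] = params_path

    if verbose:
        beam = io.load_image(paths["beam_db"])
        iz, ix = np.unravel_index(np.argmax(beam.values), beam.values.shape)
        print(f"seed {cfg.seed}  config {digest}")
        print(
            f"beam peak at x = {beam.x_grid[ix] * 1e3:+.2f} mm, "
            f"z = {beam.z_grid[iz] * 1e3:.2f} mm "
            f"(focus {fx * 1e3:+.2f}, {fz * 1e3:.2f} mm)"
        )
        print(
            f"theoretical -3 dB beamwidth {report.theoretical_beamwidth_mm:.2f} mm, "
            f"DOF {report.theoretical_dof_mm:.2f} mm (f# = {tx_f_number:.3f})"
        )
        if report.beamwidth_mm is not None:
            print(f"measured -6 dB beamwidth {report.beamwidth_mm:.2f} mm")
        if report.dof_mm is not None:
            print(f"measured -6 dB depth of field {report.dof_mm:.2f} mm")
    return {"paths": paths, "report": report, "recon": recon}


def _cfg_dict(cfg: RunConfig) -> dict:
    d = asdict(cfg)

    def clean(obj):
        if isinstance(obj, dict):
            return {k: clean(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [clean(v) for v in obj]
        if isinstance(obj, np.generic):
            return obj.item()
        return obj

    return clean(d)
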