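"""Reconstruction and run configuration, with YAML/JSON loading.

All lengths are meters, times seconds, angles of the plane-wave sequence in
degrees (converted to radians at use).  Seeds are mandatory: there is no
hidden global RNG anywhere in the package.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Tuple

import yaml

from .geometry import ArrayGeometry, make_array
from .scene import Disk, PointTarget, SceneSpec, preset_scene

__all__ = ["ReconstructionConfig", "RunConfig", "load_run_config", "config_hash"]

DEFAULT_ANGLES_DEG = (-18.0, -12.0, -6.0, 0.0, 6.0, 12.0, 18.0)


@dataclass(frozen=True)
class ReconstructionConfig:
    """Parameters of the acquisition sequence and image reconstruction.

    ``focus`` is the FUS target point; the visualization transmit is a
    ``vis_cycles``-cycle focused burst and the B-mode uses ``angles_deg``
    steered plane waves.  ``gate_db`` gates the echogenicity normalization:
    pixels whose smoothed B-mode envelope falls below this level relative to
    its maximum keep a unit normalization factor (``gate_db=None`` disables
    the gate).  Kernel sizes are in wavelengths (axial, lateral) and are
    converted to odd pixel counts at use.
    """

    focus: Tuple[float, float] = (0.0, 30e-3)
    angles_deg: Tuple[float, ...] = DEFAULT_ANGLES_DEG
    vis_cycles: int = 2
    therapy_cycles: int = 25
    rx_f_number: float = 1.0
    apodization: str = "hann"
    cf_from_apodized: bool = True
    use_cf: bool = True
    gate_db: Optional[float] = -60.0
    smooth_kernel_wl: Tuple[float, float] = (5.5, 7.0)  # axial x lateral
    median_kernel_wl: Tuple[float, float] = (5.5, 5.0)  # axial x lateral
    display_dr_bmode: float = 60.0
    display_dr_beam: float = 60.0
    overlay_threshold_db: float = -20.0
    depth_range: Tuple[float, float] = (26e-3, 34e-3)
    spreading: bool = True
    directivity: bool = False
    noise_rms: float = 0.0

    def __post_init__(self):
        if self.rx_f_number <= 0:
            raise ValueError("rx_f_number must be positive")
        if self.gate_db is not None and not self.gate_db < 0:
            raise ValueError("gate_db must be negative (dB below maximum)")
        if min(self.smooth_kernel_wl) <= 0 or min(self.median_kernel_wl) <= 0:
            raise ValueError("kernel sizes must be positive")
        if self.vis_cycles < 1:
            raise ValueError("vis_cycles must be >= 1")


@dataclass(frozen=True)
class RunConfig:
    """Everything needed for one end-to-end pipeline run."""

    array: ArrayGeometry = field(default_factory=ArrayGeometry)
    scene: SceneSpec = field(default_factory=SceneSpec)
    recon: ReconstructionConfig = field(default_factory=ReconstructionConfig)
    seed: int = 0


def _floats(seq) -> tuple:
    return tuple(float(v) for v in seq)


def _scene_from_dict(d: dict) -> SceneSpec:
    d = dict(d)
    name = d.pop("preset", None)
    regions = tuple(
        Disk(center=_floats(r["center"]), radius=float(r["radius"]),
             offset_db=float(r["offset_db"]))
        for r in d.pop("regions", ())
    )
    points = tuple(
        PointTarget(x=float(p["x"]), z=float(p["z"]),
                    level_db=float(p.get("level_db", 40.0)))
        for p in d.pop("points", ())
    )
    for key in ("x_span", "z_span"):
        if key in d:
            d[key] = _floats(d[key])
    for key in ("density", "c", "f0", "rx_f_number"):
        if key in d:
            d[key] = float(d[key])
    if regions:
        d["regions"] = regions
    if points:
        d["points"] = points
    if name is not None:
        return preset_scene(name, **d)
    return SceneSpec(**d)


def _recon_from_dict(d: dict) -> ReconstructionConfig:
    d = dict(d)
    for key in ("focus", "depth_range", "smooth_kernel_wl", "median_kernel_wl",
                "angles_deg"):
        if key in d:
            d[key] = _floats(d[key])
    for key in ("rx_f_number", "display_dr_bmode", "display_dr_beam",
                "overlay_threshold_db", "noise_rms"):
        if key in d:
            d[key] = float(d[key])
    if "gate_db" in d and d["gate_db"] is not None:
        d["gate_db"] = float(d["gate_db"])
    return ReconstructionConfig(**d)


def load_run_config(path) -> RunConfig:
    """Read a YAML (or JSON) run configuration.

    Top-level keys: ``seed`` (required), ``array``, ``scene``, ``recon``.
    The scene block may name a ``preset`` and override its fields.  Numeric
    scalars may be quoted strings (YAML 1.1 does not resolve every float
    spelling); they are coerced here.
    """
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or "seed" not in raw:
        raise ValueError(f"config {path} must be a mapping with a 'seed' key")
    array_d = {k: float(v) if k != "n_elements" else int(v)
               for k, v in raw.get("array", {}).items()}
    array = make_array(**array_d) if array_d else ArrayGeometry()
    scene = _scene_from_dict(raw.get("scene", {})) if raw.get("scene") else SceneSpec()
    recon = _recon_from_dict(raw.get("recon", {})) if raw.get("recon") else ReconstructionConfig()
    return RunConfig(array=array, scene=scene, recon=recon, seed=int(raw["seed"]))


def config_hash(cfg: RunConfig) -> str:
    """Stable sha256 digest of a run configuration (stamped on artifacts)."""

    def enc(obj):
        if dataclasses.is_dataclass(obj):
            return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, (tuple, list)):
            return [enc(v) for v in obj]
        return obj

    blob = json.dumps(enc(cfg), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
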