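"""Quantitative beam metrics and the reconstruction-fidelity MSE protocol.

Theoretical focal dimensions of a focused aperture under continuous-wave
excitation:

    R_-3dB   = 1.028 * lambda * f#          (lateral beamwidth)
    DOF_-3dB = 7.08  * lambda * f#^2        (depth of field)

with lambda the excitation wavelength and f# the transmit f-number.  Note
"lambda" here is a wavelength, distinct from the echogenicity normalization
factor.

The MSE protocol compares two intensity reconstructions: each is converted
to dB (10 log10), max-normalized, clipped to [-60, 0] dB, median-filtered
with a 5.5 x 5 wavelength (axial x lateral) window to control for speckle
variation, and the mean squared pixel difference is reported.  Values from
several homogeneous baseline reconstructions are averaged.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.ndimage import median_filter

from .beamform import BeamformedImage, _check_same_grid
from .reconstruct import wavelengths_to_odd_pixels

__all__ = [
    "MetricsReport",
    "theoretical_beamwidth",
    "theoretical_dof",
    "measure_width",
    "mse_protocol",
    "baseline_averaged_mse",
    "table_reduction",
    "validate_report",
]

MSE_CLIP_DB = (-60.0, 0.0)
MEDIAN_KERNEL_WL = (5.5, 5.0)  # axial x lateral


def theoretical_beamwidth(wavelength: float, f_number: float) -> float:
    """-3 dB beamwidth 1.028 * lambda * f# (same units as ``wavelength``)."""
    if wavelength <= 0 or f_number <= 0:
        raise ValueError("wavelength and f-number must be positive")
    return 1.028 * wavelength * f_number


def theoretical_dof(wavelength: float, f_number: float) -> float:
    """-3 dB depth of field 7.08 * lambda * f#^2."""
    if wavelength <= 0 or f_number <= 0:
        raise ValueError("wavelength and f-number must be positive")
    return 7.08 * wavelength * f_number**2


def measure_width(profile_db: np.ndarray, coords: np.ndarray, level_db: float) -> float:
    """Width of a dB profile at ``level_db`` below its peak.

    The two crossings nearest the (unique) global maximum are located by
    linear interpolation in dB.  Raises if the profile never falls below the
    level on either side of the peak.
    """
    p = np.asarray(profile_db, dtype=float)
    x = np.asarray(coords, dtype=float)
    if p.shape != x.shape or p.ndim != 1:
        raise ValueError("profile and coordinates must be matching 1-D arrays")
    if not level_db < 0:
        raise ValueError("level_db must be negative (dB below the peak)")
    ipk = int(np.argmax(p))
    thr = p[ipk] + level_db

    def cross(indices) -> float:
        prev = ipk
        for i in indices:
            if p[i] < thr:
                # linear interpolation between samples prev and i
                f = (thr - p[prev]) / (p[i] - p[prev])
                return float(x[prev] + f * (x[i] - x[prev]))
            prev = i
        raise ValueError(f"profile never crosses {level_db:+g} dB on one side of the peak")

    left = cross(range(ipk - 1, -1, -1))
    right = cross(range(ipk + 1, len(p)))
    return right - left


def _mse_preprocess(img: BeamformedImage, wavelength: float) -> np.ndarray:
    if img.kind not in ("intensity", "intensity_norm"):
        raise ValueError("MSE protocol expects intensity-kind images")
    v = img.values
    vmax = v.max()
    if not vmax > 0:
        raise ValueError("cannot compare an all-zero intensity image")
    with np.errstate(divide="ignore"):
        db = 10.0 * np.log10(v / vmax)
    db = np.clip(db, MSE_CLIP_DB[0], MSE_CLIP_DB[1])
    k_ax = wavelengths_to_odd_pixels(MEDIAN_KERNEL_WL[0], wavelength, img.dz)
    k_lat = wavelengths_to_odd_pixels(MEDIAN_KERNEL_WL[1], wavelength, img.dx)
    return median_filter(db, size=(k_ax, k_lat), mode="reflect")


def mse_protocol(
    recon_a: BeamformedImage, recon_b: BeamformedImage, wavelength: float
) -> float:
    """MSE between two intensity reconstructions after dB conversion,
    max-normalization, clipping to [-60, 0] dB and median filtering."""
    _check_same_grid(recon_a, recon_b)
    a = _mse_preprocess(recon_a, wavelength)
    b = _mse_preprocess(recon_b, wavelength)
    return float(np.mean((a - b) ** 2))


def baseline_averaged_mse(
    target: BeamformedImage,
    baselines: Sequence[BeamformedImage],
    wavelength: float,
) -> float:
    """Mean of ``mse_protocol(target, b)`` over several baseline
    reconstructions from homogeneous regions."""
    if not baselines:
        raise ValueError("need at least one baseline reconstruction")
    return float(np.mean([mse_protocol(target, b, wavelength) for b in baselines]))


def table_reduction(original: Sequence[float], normalized: Sequence[float]) -> float:
    """Mean reduction ``mean(original_i - normalized_i)`` across regions."""
    o = np.asarray(original, dtype=float)
    n = np.asarray(normalized, dtype=float)
    if o.shape != n.shape:
        raise ValueError("original and normalized lists must have equal length")
    return float(np.mean(o - n))


@dataclass(frozen=True)
class MetricsReport:
    """Beam metrics for one reconstruction."""

    wavelength_mm: float
    f_number: float
    theoretical_beamwidth_mm: float
    theoretical_dof_mm: float
    level_db: float = -6.0
    beamwidth_mm: Optional[float] = None
    dof_mm: Optional[float] = None
    mse: Optional[float] = None
    mse_normalized: Optional[float] = None
    n_baselines: int = 0

    def to_json(self, path=None) -> str:
        blob = json.dumps(asdict(self), indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(blob + "\n")
        return blob


#: minimal schema for a serialized MetricsReport (checked by validate_report)
REPORT_SCHEMA = {
    "required": {
        "wavelength_mm": (int, float),
        "f_number": (int, float),
        "theoretical_beamwidth_mm": (int, float),
        "theoretical_dof_mm": (int, float),
        "level_db": (int, float),
        "n_baselines": int,
    },
    "optional": {
        "beamwidth_mm": (int, float, type(None)),
        "dof_mm": (int, float, type(None)),
        "mse": (int, float, type(None)),
        "mse_normalized": (int, float, type(None)),
    },
}


def validate_report(report: dict) -> None:
    """Check a deserialized report against :data:`REPORT_SCHEMA`."""
    for key, types in REPORT_SCHEMA["required"].items():
        if key not in report:
            raise ValueError(f"metrics report missing required key {key!r}")
        if not isinstance(report[key], types):
            raise ValueError(f"metrics report key {key!r} has wrong type")
    for key, types in REPORT_SCHEMA["optional"].items():
        if key in report and not isinstance(report[key], types):
            raise ValueError(f"metrics report key {key!r} has wrong type")
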