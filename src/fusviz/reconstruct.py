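"""FUS intensity-field reconstruction and echogenicity normalization.

The beam intensity is a sliding pulse-intensity integral of the CF-weighted
beamformed data along each scan line:

    I(x, z) = sum_{i=0..L-1} dz |y_CF(x, z + i)|^2

with L the visualization-pulse length in samples and dz the axial sampling
period.  Variations in the medium's scattering strength are then equalized
using the coaligned B-mode image: its linear envelope is smoothed with a
5.5 x 7 wavelength (axial x lateral) moving-average kernel, a normalization
factor lam(x, z) = B_max / B(x, z) is formed (unity where B falls below the
gate, default -60 dB relative to its maximum), and

    I_norm(x, z) = I(x, z) * L * lam(x, z)^2.

The factor L and the squared lam mirror the L-sample integral of squared
beamformed data; under max-normalization the global constant L cancels.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property
from typing import Optional, Tuple

import numpy as np
from scipy.ndimage import uniform_filter

from .beamform import (
    BeamformedImage,
    DASResult,
    _check_same_grid,
    apply_cf,
    compound,
    das_focused,
    das_plane_wave,
    envelope,
    log_compress,
)
from .config import ReconstructionConfig
from .simulate import AcquisitionResult

__all__ = [
    "intensity_field",
    "smooth_bmode",
    "normalization_factor",
    "normalize_intensity",
    "make_overlay",
    "wavelengths_to_odd_pixels",
    "BeamReconstruction",
    "reconstruct_acquisition",
]


def wavelengths_to_odd_pixels(extent_wl: float, wavelength: float, step: float) -> int:
    """Convert a kernel extent in wavelengths to the nearest odd pixel count
    (>= 1) for a grid with spacing ``step``."""
    if extent_wl <= 0 or wavelength <= 0 or step <= 0:
        raise ValueError("kernel extent, wavelength and grid step must be positive")
    n = extent_wl * wavelength / step
    return max(1, 2 * int(round((n - 1) / 2.0)) + 1)


def intensity_field(y_cf: BeamformedImage, L: int, dz: Optional[float] = None) -> BeamformedImage:
    """Sliding axial pulse-intensity integral of the beamformed data.

    The L-sample window starts at each point and extends toward depth; it is
    truncated (zero-padded) at the deep edge.
    """
    if y_cf.kind not in ("y", "y_cf"):
        raise ValueError(f"intensity_field expects RF-domain data, got {y_cf.kind!r}")
    if L < 1:
        raise ValueError("pulse length L must be >= 1")
    n_z = y_cf.values.shape[0]
    if L > n_z:
        raise ValueError(f"pulse length L={L} exceeds the axial extent ({n_z})")
    if dz is None:
        dz = y_cf.dz
    sq = y_cf.values**2
    padded = np.vstack([sq, np.zeros((L - 1, sq.shape[1]))]) if L > 1 else sq
    csum = np.cumsum(padded, axis=0)
    win = csum[L - 1 :, :].copy()
    win[1:, :] -= csum[: n_z - 1, :]
    return y_cf.with_values(dz * win, kind="intensity")


def smooth_bmode(
    env: BeamformedImage, kernel_wavelengths: Tuple[float, float], wavelength: float
) -> BeamformedImage:
    """Moving-average smoothing of the linear B-mode envelope.

    ``kernel_wavelengths`` is (axial, lateral) in wavelengths, converted to
    odd pixel counts; edges are handled by reflection.
    """
    if env.kind not in ("envelope", "bmode"):
        raise ValueError("smooth_bmode expects a linear envelope image")
    k_ax = wavelengths_to_odd_pixels(kernel_wavelengths[0], wavelength, env.dz)
    k_lat = wavelengths_to_odd_pixels(kernel_wavelengths[1], wavelength, env.dx)
    if k_ax > env.values.shape[0] or k_lat > env.values.shape[1]:
        raise ValueError(
            f"smoothing kernel ({k_ax} x {k_lat} px) exceeds the image "
            f"{env.values.shape}"
        )
    sm = uniform_filter(env.values, size=(k_ax, k_lat), mode="reflect")
    return env.with_values(sm, kind="bmode")


def normalization_factor(B: BeamformedImage, gate_db: Optional[float] = -60.0) -> BeamformedImage:
    """Echogenicity normalization factor lam = B_max / B.

    Points where B falls below ``gate_db`` relative to its maximum (assumed
    noise rather than backscatter) keep lam = 1; ``gate_db=None`` disables
    the gate, in which case only exact zeros of B keep lam = 1.
    """
    v = B.values
    bmax = v.max()
    if not bmax > 0:
        raise ValueError("cannot normalize by an all-zero B-mode image")
    if gate_db is not None:
        gated = v < bmax * 10.0 ** (gate_db / 20.0)
    else:
        gated = v == 0.0
    lam = np.ones_like(v)
    np.divide(bmax, v, out=lam, where=~gated)
    return B.with_values(lam, kind="lambda")


def normalize_intensity(I: BeamformedImage, lam: BeamformedImage, L: int) -> BeamformedImage:
    """I_norm(x, z) = I(x, z) * L * lam(x, z)^2."""
    _check_same_grid(I, lam)
    if L < 1:
        raise ValueError("pulse length L must be >= 1")
    return I.with_values(I.values * L * lam.values**2, kind="intensity_norm")


def make_overlay(
    bmode_db: BeamformedImage,
    beam_db: BeamformedImage,
    threshold_db: float = -20.0,
    bmode_dynamic_range: float = 60.0,
    beam_cmap: str = "hot",
    path=None,
) -> np.ndarray:
    """Compose the beam visualization over the grayscale B-mode.

    Beam pixels at or above ``threshold_db`` are rendered in a warm colormap
    with opacity ramping linearly from 0 at the threshold to 1 at 0 dB;
    pixels below the threshold are fully transparent.  Returns an RGBA float
    array (n_z, n_x, 4); optionally writes a PNG.
    """
    _check_same_grid(bmode_db, beam_db)
    import matplotlib

    gray = np.clip(1.0 + bmode_db.values / bmode_dynamic_range, 0.0, 1.0)
    base = np.repeat(gray[:, :, None], 3, axis=2)
    if np.isneginf(threshold_db):
        alpha = np.ones_like(beam_db.values)
        level = np.clip(1.0 + beam_db.values / 60.0, 0.0, 1.0)
    else:
        alpha = np.clip(
            (beam_db.values - threshold_db) / (0.0 - threshold_db), 0.0, 1.0
        )
        level = alpha
    cmap = matplotlib.colormaps[beam_cmap]
    beam_rgb = cmap(level)[:, :, :3]
    out = np.empty(base.shape[:2] + (4,))
    out[:, :, :3] = (1.0 - alpha[:, :, None]) * base + alpha[:, :, None] * beam_rgb
    out[:, :, 3] = 1.0
    if path is not None:
        import matplotlib.image

        matplotlib.image.imsave(str(path), np.clip(out, 0, 1))
    return out


@dataclass(frozen=True)
class BeamReconstruction:
    """All reconstruction products for one acquisition.

    Built once from the RF frames; intensity variants (with/without CF
    weighting, with/without echogenicity normalization, custom gate) are
    derived on demand so beamforming is not repeated.
    """

    das: DASResult  # focused-frame DAS (y + CF map)
    bmode_env: BeamformedImage  # compounded plane-wave envelope (linear)
    config: ReconstructionConfig
    wavelength: float
    pulse_len: int  # L, visualization pulse length in samples

    @cached_property
    def y_cf(self) -> BeamformedImage:
        return apply_cf(self.das.y, self.das.cf)

    @cached_property
    def bmode_smooth(self) -> BeamformedImage:
        return smooth_bmode(self.bmode_env, self.config.smooth_kernel_wl, self.wavelength)

    def bmode_db(self) -> BeamformedImage:
        return log_compress(self.bmode_env, -self.config.display_dr_bmode)

    def lam(self, gate_db="config") -> BeamformedImage:
        if gate_db == "config":
            gate_db = self.config.gate_db
        return normalization_factor(self.bmode_smooth, gate_db)

    def intensity(
        self, use_cf: bool = True, normalized: bool = True, gate_db="config"
    ) -> BeamformedImage:
        y = self.y_cf if use_cf else self.das.y
        I = intensity_field(y, self.pulse_len)
        if not normalized:
            return I
        return normalize_intensity(I, self.lam(gate_db), self.pulse_len)

    def beam_db(
        self, use_cf: bool = True, normalized: bool = True, gate_db="config"
    ) -> BeamformedImage:
        return log_compress(
            self.intensity(use_cf, normalized, gate_db), -self.config.display_dr_beam
        )

    def overlay(self, path=None) -> np.ndarray:
        return make_overlay(
            self.bmode_db(),
            self.beam_db(use_cf=self.config.use_cf),
            self.config.overlay_threshold_db,
            self.config.display_dr_bmode,
            path=path,
        )


def reconstruct_acquisition(
    acq: AcquisitionResult, config: Optional[ReconstructionConfig] = None
) -> BeamReconstruction:
    """Beamform an acquisition into a :class:`BeamReconstruction`.

    The focused visualization frame is DAS-beamformed with a dynamic receive
    aperture (its CF map retained); the plane-wave frames are beamformed on
    the same grid and coherently compounded into the B-mode envelope.
    """
    if config is None:
        config = acq.config
    array = acq.array
    z0, z1 = config.depth_range
    z_grid = np.arange(z0, z1, array.dz)
    peak = acq.pulse.peak_time
    das = das_focused(
        acq.focused,
        array,
        z_grid,
        f_number=config.rx_f_number,
        apodization=config.apodization,
        cf_from_apodized=config.cf_from_apodized,
        wavelet_peak_time=peak,
    )
    pw_images = [
        das_plane_wave(
            frame,
            array,
            frame.tx.angle,
            z_grid,
            f_number=config.rx_f_number,
            apodization=config.apodization,
            wavelet_peak_time=peak,
        ).y
        for frame in acq.plane_waves
    ]
    bmode_env = envelope(compound(pw_images))
    return BeamReconstruction(
        das=das,
        bmode_env=bmode_env,
        config=config,
        wavelength=array.wavelength,
        pulse_len=acq.pulse.n_samples,
    )
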