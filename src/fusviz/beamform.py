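"""Delay-and-sum beamforming with dynamic receive focusing, coherence-factor
weighting, plane-wave compounding, envelope detection and log compression.

The image grid places one lateral line at each array element position and
samples depth at dz = c/(2 fs), matching the RF sampling.  The receive
subaperture grows with depth at a fixed f-number (half-width z / (2 f#)),
clipped at the array edges, and is apodized with a Hanning window defined
over the full nominal subaperture width.  Subsample delays use linear
interpolation.

The coherence factor CF = |sum_i s_i|^2 / (N sum_i |s_i|^2) is the ratio of
coherent to incoherent energy across the N subaperture channels; it lies in
[0, 1] (Cauchy-Schwarz) and multiplies the DAS output pointwise to suppress
sidelobe and clutter signal.  By default the CF is computed from the same
Hanning-apodized delayed samples that feed the sum (switchable to raw
samples with ``cf_from_apodized=False``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.signal import hilbert

from .geometry import ArrayGeometry
from .simulate import RFFrame

__all__ = [
    "BeamformedImage",
    "DASResult",
    "receive_delay",
    "das_focused",
    "das_plane_wave",
    "coherence_factor",
    "apply_cf",
    "compound",
    "envelope",
    "log_compress",
]

_RF_KINDS = {"y", "y_cf"}
_ENVELOPE_KINDS = {"envelope", "bmode"}
_INTENSITY_KINDS = {"intensity", "intensity_norm"}


@dataclass(frozen=True)
class BeamformedImage:
    """A gridded image: ``values`` is (n_z, n_x) over ``z_grid`` x ``x_grid``.

    ``kind`` tags the value domain: ``y``/``y_cf`` (real RF-beamformed),
    ``cf_map`` (in [0,1]), ``envelope``/``bmode`` (nonnegative), ``intensity``/
    ``intensity_norm`` (nonnegative), ``db`` (max-normalized, <= 0).
    """

    values: np.ndarray
    x_grid: np.ndarray
    z_grid: np.ndarray
    kind: str

    def __post_init__(self):
        if self.values.shape != (self.z_grid.size, self.x_grid.size):
            raise ValueError(
                f"values shape {self.values.shape} does not match grid "
                f"({self.z_grid.size}, {self.x_grid.size})"
            )
        for g in (self.x_grid, self.z_grid):
            if g.size > 1 and not np.all(np.diff(g) > 0):
                raise ValueError("image grids must be strictly increasing")

    @property
    def dz(self) -> float:
        return float(self.z_grid[1] - self.z_grid[0])

    @property
    def dx(self) -> float:
        return float(self.x_grid[1] - self.x_grid[0])

    def with_values(self, values: np.ndarray, kind: Optional[str] = None) -> "BeamformedImage":
        return BeamformedImage(values, self.x_grid, self.z_grid, kind or self.kind)


def _check_same_grid(a: BeamformedImage, b: BeamformedImage) -> None:
    if a.values.shape != b.values.shape or not (
        np.array_equal(a.x_grid, b.x_grid) and np.array_equal(a.z_grid, b.z_grid)
    ):
        raise ValueError("images are defined on different grids")


@dataclass(frozen=True)
class DASResult:
    """DAS output: beamformed image, coherence-factor map, and (optionally)
    the un-summed delayed/apodized subaperture samples (n_z, n_x, n_elem)."""

    y: BeamformedImage
    cf: BeamformedImage
    channels: Optional[np.ndarray] = None

    def y_cf(self) -> BeamformedImage:
        return apply_cf(self.y, self.cf)


def receive_delay(x, x_c, z, c: float, tau_f: float = 0.0):
    """Two-way time of flight for dynamic receive focusing.

    tau(x, z) = tau_F(x_c) + (z + sqrt(z^2 + (x - x_c)^2)) / c

    where ``x`` is the receiving element position, ``x_c`` the image line,
    ``z`` the depth and ``tau_F`` the transmit delay of the line's center
    element.  Accepts scalars or broadcastable arrays.
    """
    z = np.asarray(z, dtype=float)
    if np.any(z <= 0):
        raise ValueError("depth z must be strictly positive")
    return tau_f + (z + np.sqrt(z**2 + (np.asarray(x, float) - x_c) ** 2)) / c


def _aperture_weights(
    elem_x: np.ndarray, x_c: float, z: np.ndarray, f_number: float, apodization: str
) -> np.ndarray:
    """(n_z, n_el) apodization weights of the dynamic receive subaperture."""
    half = z[:, None] / (2.0 * f_number)
    u = (elem_x[None, :] - x_c) / half
    inside = np.abs(u) <= 1.0
    if apodization in ("hann", "hanning"):
        w = np.where(inside, 0.5 + 0.5 * np.cos(np.pi * np.clip(u, -1, 1)), 0.0)
    elif apodization in ("rect", "boxcar", "uniform"):
        w = inside.astype(float)
    else:
        raise ValueError(f"unknown apodization {apodization!r}")
    return w


def _gather(data: np.ndarray, idx: np.ndarray) -> Tuple[np.ndarray, bool]:
    """Linearly interpolate each channel of ``data`` (n_t, n_el) at the
    fractional sample positions ``idx`` (n_z, n_el); zero outside record."""
    n_t = data.shape[0]
    i0 = np.floor(idx).astype(np.int64)
    frac = idx - i0
    valid = (i0 >= 0) & (i0 <= n_t - 2)
    i0c = np.clip(i0, 0, n_t - 2)
    cols = np.arange(data.shape[1])[None, :]
    s = data[i0c, cols] * (1.0 - frac) + data[i0c + 1, cols] * frac
    s[~valid] = 0.0
    return s, bool(valid.all())


def _das_lines(
    rf: RFFrame,
    array: ArrayGeometry,
    z_grid: np.ndarray,
    tx_time_of_line,  # callable line_index, z -> transmit time (n_z,)
    f_number: float,
    apodization: str,
    cf_from_apodized: bool,
    wavelet_peak_time: float,
    store_channels: bool,
) -> DASResult:
    elem_x = array.element_x
    x_grid = elem_x.copy()
    n_z, n_x = z_grid.size, x_grid.size
    y = np.zeros((n_z, n_x))
    cf = np.zeros((n_z, n_x))
    channels = np.zeros((n_z, n_x, array.n_elements)) if store_channels else None
    all_inside = True
    for ci, xc in enumerate(x_grid):
        t_tx = tx_time_of_line(ci, z_grid)  # (n_z,)
        t_rx = np.sqrt(z_grid[:, None] ** 2 + (xc - elem_x[None, :]) ** 2) / array.c
        tau = t_tx[:, None] + t_rx + wavelet_peak_time
        idx = (tau - rf.t0) * rf.fs
        s, ok = _gather(rf.data, idx)
        all_inside &= ok
        w = _aperture_weights(elem_x, xc, z_grid, f_number, apodization)
        sw = s * w
        y[:, ci] = sw.sum(axis=1)
        mask = w > 0
        n_used = mask.sum(axis=1)
        sc = sw if cf_from_apodized else s * mask
        num = sc.sum(axis=1) ** 2
        den = n_used * (sc**2).sum(axis=1)
        cf[:, ci] = np.divide(num, den, out=np.zeros(n_z), where=den > 0)
        if store_channels:
            channels[:, ci, :] = sw
    if not all_inside:
        warnings.warn(
            "image grid extends outside the RF record window; out-of-window "
            "samples were zero-filled",
            RuntimeWarning,
            stacklevel=3,
        )
    return DASResult(
        y=BeamformedImage(y, x_grid, z_grid.copy(), "y"),
        cf=BeamformedImage(cf, x_grid, z_grid.copy(), "cf_map"),
        channels=channels,
    )


def das_focused(
    rf: RFFrame,
    array: ArrayGeometry,
    z_grid: np.ndarray,
    f_number: float = 1.0,
    apodization: str = "hann",
    *,
    cf_from_apodized: bool = True,
    wavelet_peak_time: float = 0.0,
    store_channels: bool = False,
) -> DASResult:
    """DAS reconstruction of a focused-transmit frame, one line per element.

    The transmit time of line ``x_c`` at depth ``z`` is modeled as
    ``tau_F(x_c) + z/c`` with ``tau_F`` the transmit delay of the line's
    element — exact at the transmit focus.  ``wavelet_peak_time`` shifts the
    delay law onto the echo peak (pass ``pulse.peak_time``).
    """
    if rf.tx.kind != "focused":
        raise ValueError("das_focused requires a focused transmit event")
    if f_number <= 0:
        raise ValueError("f_number must be positive")
    z_grid = np.asarray(z_grid, dtype=float)
    if np.any(z_grid <= 0):
        raise ValueError("depth grid must be strictly positive")
    delays = rf.tx.delays

    def tx_time(ci, z):
        return delays[ci] + z / array.c

    return _das_lines(
        rf, array, z_grid, tx_time, f_number, apodization,
        cf_from_apodized, wavelet_peak_time, store_channels,
    )


def das_plane_wave(
    rf: RFFrame,
    array: ArrayGeometry,
    angle: float,
    z_grid: np.ndarray,
    f_number: float = 1.0,
    apodization: str = "hann",
    *,
    cf_from_apodized: bool = True,
    wavelet_peak_time: float = 0.0,
    store_channels: bool = False,
) -> DASResult:
    """DAS reconstruction of a steered plane-wave frame on the common grid.

    The transmit wavefront reaches (x, z) at ``(z cos(a) + x sin(a) - m)/c``
    where ``m = min_e x_e sin(a)`` accounts for the delay normalization that
    makes the earliest element fire at t = 0.
    """
    if rf.tx.kind != "plane_wave":
        raise ValueError("das_plane_wave requires a plane-wave transmit event")
    if f_number <= 0:
        raise ValueError("f_number must be positive")
    z_grid = np.asarray(z_grid, dtype=float)
    if np.any(z_grid <= 0):
        raise ValueError("depth grid must be strictly positive")
    sin_a, cos_a = np.sin(angle), np.cos(angle)
    m = np.min(array.element_x * sin_a)
    x_grid = array.element_x

    def tx_time(ci, z):
        return (z * cos_a + x_grid[ci] * sin_a - m) / array.c

    return _das_lines(
        rf, array, z_grid, tx_time, f_number, apodization,
        cf_from_apodized, wavelet_peak_time, store_channels,
    )


def coherence_factor(samples: np.ndarray, axis: int = -1) -> np.ndarray:
    """CF = |sum_i s_i|^2 / (N sum_i |s_i|^2) along ``axis``; 0 where the
    subaperture carries no energy."""
    s = np.asarray(samples, dtype=float)
    n = s.shape[axis]
    if n < 1:
        raise ValueError("subaperture must contain at least one channel")
    num = s.sum(axis=axis) ** 2
    den = n * (s**2).sum(axis=axis)
    return np.divide(num, den, out=np.zeros_like(np.asarray(den, dtype=float)), where=den > 0)


def apply_cf(y: BeamformedImage, cf_map: BeamformedImage) -> BeamformedImage:
    """Pointwise CF weighting: y_CF(x, z) = CF(x, z) y(x, z)."""
    _check_same_grid(y, cf_map)
    return y.with_values(y.values * cf_map.values, kind="y_cf")


def compound(images: Sequence[BeamformedImage]) -> BeamformedImage:
    """Coherent (pre-envelope, RF-domain) compounding: pointwise sum."""
    if not images:
        raise ValueError("need at least one image to compound")
    first = images[0]
    total = first.values.copy()
    for img in images[1:]:
        _check_same_grid(first, img)
        total += img.values
    return first.with_values(total, kind=first.kind)


def envelope(y: BeamformedImage) -> BeamformedImage:
    """Magnitude of the analytic signal along depth, per image line."""
    if y.kind not in _RF_KINDS:
        raise ValueError(f"envelope expects RF-domain values, got kind {y.kind!r}")
    env = np.abs(hilbert(y.values, axis=0))
    return y.with_values(env, kind="envelope")


def log_compress(img: BeamformedImage, floor_db: float = -60.0) -> BeamformedImage:
    """Max-normalized log compression, clipped below at ``floor_db``.

    Amplitude-domain inputs (envelope, B-mode, CF) use 20 log10; power-domain
    inputs (intensity) use 10 log10.  The maximum pixel maps to 0 dB.
    """
    if img.kind in _RF_KINDS:
        raise ValueError("log_compress expects nonnegative envelope/intensity values")
    factor = 10.0 if img.kind in _INTENSITY_KINDS else 20.0
    vmax = img.values.max()
    if not vmax > 0:
        raise ValueError("cannot log-compress an all-zero image")
    with np.errstate(divide="ignore"):
        db = factor * np.log10(img.values / vmax)
    return img.with_values(np.clip(db, floor_db, 0.0), kind="db")
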