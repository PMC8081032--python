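"""Linear-array geometry, excitation pulses and transmit delay laws.

The imaging probe is modeled as a 1-D linear array of point-like elements
on the lateral (x) axis, with imaging depth along z.  Defaults describe a
128-element, 5 MHz array (L9-4/38 class probe, 0.3048 mm pitch) sampled at
four samples per wavelength (20 MHz), in soft tissue (c = 1540 m/s).

Time zero is defined as the firing of the earliest element: every transmit
delay law is shifted so its minimum is exactly zero.  The simulator and the
beamformer share this origin.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

__all__ = [
    "ArrayGeometry",
    "PulseSpec",
    "TransmitEvent",
    "make_array",
    "make_pulse",
    "focused_delays",
    "plane_wave_delays",
]


@dataclass(frozen=True)
class ArrayGeometry:
    """Geometry and sampling of a linear imaging array.

    Attributes
    ----------
    n_elements : int
        Number of elements (default 128).
    pitch : float
        Element spacing in meters (default 0.3048 mm).
    f0 : float
        Center frequency in Hz (default 5 MHz).
    fs : float
        RF sampling rate in Hz (default 20 MHz, i.e. four samples per
        wavelength at ``f0``).
    c : float
        Speed of sound in m/s (default 1540; use 1480 for water scenes).
    """

    n_elements: int = 128
    pitch: float = 0.3048e-3
    f0: float = 5e6
    fs: float = 20e6
    c: float = 1540.0

    @property
    def element_x(self) -> np.ndarray:
        """Lateral element positions (m), uniformly spaced, centered on 0."""
        return (np.arange(self.n_elements) - (self.n_elements - 1) / 2.0) * self.pitch

    @property
    def aperture(self) -> float:
        """Full aperture span ``(n_elements - 1) * pitch`` in meters."""
        return (self.n_elements - 1) * self.pitch

    @property
    def wavelength(self) -> float:
        return self.c / self.f0

    @property
    def dz(self) -> float:
        """Axial sample spacing ``c / (2 fs)`` of an RF-sampled image grid."""
        return self.c / (2.0 * self.fs)


def make_array(
    n_elements: int = 128,
    pitch: float = 0.3048e-3,
    f0: float = 5e6,
    fs: float = 20e6,
    c: float = 1540.0,
) -> ArrayGeometry:
    """Build an :class:`ArrayGeometry`, validating physical parameters."""
    if n_elements < 2:
        raise ValueError(f"need at least 2 elements, got {n_elements}")
    for name, v in (("pitch", pitch), ("f0", f0), ("fs", fs), ("c", c)):
        if not (v > 0) or not math.isfinite(v):
            raise ValueError(f"{name} must be a positive finite number, got {v!r}")
    if fs < 2 * f0:
        raise ValueError(f"fs={fs:g} violates the Nyquist rate for f0={f0:g}")
    return ArrayGeometry(int(n_elements), float(pitch), float(f0), float(fs), float(c))


@dataclass(frozen=True)
class PulseSpec:
    """A tone-burst excitation (jointly modeling the two-way electromechanical
    response of the probe as a single band-limited wavelet).

    ``n_cycles=2`` is the beam-visualization pulse; ``n_cycles=25`` the mock
    therapy burst.  ``window`` tapers the burst envelope: ``"raised_cosine"``
    (default, a smooth Hann-like taper over the burst duration) or ``"rect"``.
    """

    n_cycles: int
    f0: float
    fs: float
    window: str = "raised_cosine"
    amplitude: float = 1.0

    @property
    def duration(self) -> float:
        """Burst duration ``n_cycles / f0`` in seconds."""
        return self.n_cycles / self.f0

    @property
    def n_samples(self) -> int:
        """Pulse length L in samples at ``fs`` (>= 1)."""
        return max(1, round(self.n_cycles * self.fs / self.f0))

    @property
    def samples(self) -> np.ndarray:
        """The sampled wavelet, peak absolute value equal to ``amplitude``."""
        L = self.n_samples
        # sample at bin centers so the taper never evaluates to exactly zero
        t = (np.arange(L) + 0.5) / self.fs
        s = np.sin(2.0 * np.pi * self.f0 * t)
        if self.window in ("raised_cosine", "hann", "hanning"):
            s = s * (0.5 - 0.5 * np.cos(2.0 * np.pi * t / self.duration))
        elif self.window in ("rect", "boxcar", "none"):
            pass
        else:
            raise ValueError(f"unknown window {self.window!r}")
        peak = np.max(np.abs(s))
        if peak > 0:
            s = s * (self.amplitude / peak)
        return s

    @property
    def peak_time(self) -> float:
        """Time of the wavelet's absolute peak (s); used to center the
        beamformer's delay law on the echo peak rather than its onset."""
        return float(np.argmax(np.abs(self.samples))) / self.fs


def make_pulse(
    n_cycles: int = 2,
    f0: float = 5e6,
    fs: float = 20e6,
    window: str = "raised_cosine",
    amplitude: float = 1.0,
) -> PulseSpec:
    """Build a :class:`PulseSpec`; rejects sampling below the Nyquist rate."""
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    if fs <= 2 * f0:
        raise ValueError(f"fs={fs:g} <= 2*f0={2 * f0:g}: tone burst would alias")
    return PulseSpec(int(n_cycles), float(f0), float(fs), window, float(amplitude))


@dataclass(frozen=True)
class TransmitEvent:
    """One transmit firing: per-element delays plus a focus or steering tag.

    ``delays`` are nonnegative with ``min(delays) == 0`` (time zero is the
    earliest-firing element).
    """

    kind: str  # "focused" | "plane_wave"
    delays: np.ndarray
    focus: Optional[Tuple[float, float]] = None
    angle: Optional[float] = None


def focused_delays(array: ArrayGeometry, focus: Tuple[float, float]) -> TransmitEvent:
    """Transmit delay law focusing all elements on a point ``(x, z)``.

    Delays equalize the time of flight so all wavefronts arrive at the
    focus simultaneously: ``delays[e] = (max_e' d(e') - d(e)) / c``.
    """
    fx, fz = float(focus[0]), float(focus[1])
    if not fz > 0:
        raise ValueError(f"focus depth must be positive, got z={fz!r}")
    d = np.hypot(array.element_x - fx, fz)
    delays = (d.max() - d) / array.c
    return TransmitEvent(kind="focused", delays=delays, focus=(fx, fz))


def plane_wave_delays(array: ArrayGeometry, angle: float) -> TransmitEvent:
    """Transmit delay law steering a plane wave by ``angle`` radians.

    Delays are affine in element position with slope ``sin(angle)/c``,
    shifted so the earliest element fires at t = 0.
    """
    angle = float(angle)
    if not abs(angle) < np.pi / 2:
        raise ValueError("steering angle must satisfy |angle| < 90 degrees")
    raw = array.element_x * np.sin(angle) / array.c
    return TransmitEvent(kind="plane_wave", delays=raw - raw.min(), angle=angle)
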