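"""Point-scatterer RF channel-data simulator.

Each transmit event fires all elements with its delay law; every scatterer
re-radiates the two-way wavelet, which is received by every element.  The
spatial impulse responses of the physical elements are approximated by
point-element superposition with optional 1/r spherical spreading per path
(default on) and a hard-baffle cosine directivity factor (default off).
Nonlinear propagation, multiple scattering and dispersive attenuation are
not modeled.

The record window starts at t = 0 (firing of the earliest element) and by
default covers the farthest round trip plus the pulse duration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np

from ._kernels import superpose_echoes
from .config import ReconstructionConfig
from .geometry import (
    ArrayGeometry,
    PulseSpec,
    TransmitEvent,
    focused_delays,
    make_pulse,
    plane_wave_delays,
)
from .scene import ScattererField

__all__ = [
    "RFFrame",
    "SimOptions",
    "AcquisitionResult",
    "simulate_rf",
    "simulate_acquisition",
]


@dataclass(frozen=True)
class SimOptions:
    """Propagation-model switches for the simulator."""

    spreading: bool = True  # 1/r one-way amplitude decay per path
    directivity: bool = False  # cos(theta) hard-baffle element factor
    noise_rms: float = 0.0  # additive white sensor noise (linear units)

    def __post_init__(self):
        if self.noise_rms < 0:
            raise ValueError("noise_rms must be nonnegative")


@dataclass(frozen=True)
class RFFrame:
    """Per-channel RF record for one transmit event.

    ``data`` is (n_samples, n_elements); ``t0`` is the time of the first
    sample relative to the transmit origin (the earliest-firing element).
    """

    data: np.ndarray
    fs: float
    t0: float
    tx: TransmitEvent
    truncated: bool = False


def _record_samples(
    array: ArrayGeometry,
    tx: TransmitEvent,
    pulse: PulseSpec,
    scene: ScattererField,
    min_record_time: float = 0.0,
) -> int:
    """Samples needed to cover every echo, with a small safety margin."""
    if len(scene) == 0:
        t_end = float(tx.delays.max()) + pulse.duration
    else:
        xe = array.element_x
        # elements are colinear: the farthest element from any scatterer is
        # one of the two ends
        d_far = np.maximum(
            np.hypot(scene.x - xe[0], scene.z), np.hypot(scene.x - xe[-1], scene.z)
        )
        t_end = float(tx.delays.max()) + 2.0 * float(d_far.max()) / array.c + pulse.duration
    t_end = max(t_end, min_record_time)
    return int(np.ceil(t_end * array.fs)) + 16


def simulate_rf(
    array: ArrayGeometry,
    tx: TransmitEvent,
    pulse: PulseSpec,
    scene: ScattererField,
    opts: SimOptions = SimOptions(),
    seed: Optional[int] = None,
    n_samples: Optional[int] = None,
    min_record_time: float = 0.0,
) -> RFFrame:
    """Simulate one RF frame.

    The output is linear in scatterer amplitudes and deterministic for a
    fixed seed (the seed only feeds the additive sensor noise).  If an
    explicit ``n_samples`` cuts off part of an echo, a truncation warning is
    issued and the frame is flagged.
    """
    if tx.delays.shape != (array.n_elements,):
        raise ValueError("transmit delays do not match the array")
    if len(scene) and not np.all(np.isfinite(scene.amplitude)):
        raise ValueError("scene contains non-finite amplitudes")

    n_t = (
        int(n_samples)
        if n_samples is not None
        else _record_samples(array, tx, pulse, scene, min_record_time)
    )
    data = np.zeros((n_t, array.n_elements), dtype=np.float64)
    truncated = False
    if len(scene):
        clipped = superpose_echoes(
            data,
            float(array.fs),
            np.ascontiguousarray(array.element_x, dtype=np.float64),
            np.ascontiguousarray(tx.delays, dtype=np.float64),
            np.ascontiguousarray(scene.x, dtype=np.float64),
            np.ascontiguousarray(scene.z, dtype=np.float64),
            np.ascontiguousarray(scene.amplitude, dtype=np.float64),
            np.ascontiguousarray(pulse.samples, dtype=np.float64),
            1.0 / scene.c,
            bool(opts.spreading),
            bool(opts.directivity),
        )
        if clipped:
            truncated = True
            warnings.warn(
                f"record window too short: {clipped} echo samples truncated",
                RuntimeWarning,
                stacklevel=2,
            )
    if opts.noise_rms > 0:
        rng = np.random.default_rng(seed)
        data += rng.normal(0.0, opts.noise_rms, size=data.shape)
    return RFFrame(data=data, fs=array.fs, t0=0.0, tx=tx, truncated=truncated)


@dataclass(frozen=True)
class AcquisitionResult:
    """Output of one full excitation sequence over a scene.

    ``frames[0]`` is the focused visualization frame; ``frames[1:]`` are the
    steered plane-wave frames in the order of ``config.angles_deg``.  The
    mock therapy burst appears in ``log`` but produces no frame.
    """

    frames: List[RFFrame]
    log: List[dict]
    array: ArrayGeometry
    pulse: PulseSpec  # the visualization pulse
    config: ReconstructionConfig
    seed: int

    @property
    def focused(self) -> RFFrame:
        return self.frames[0]

    @property
    def plane_waves(self) -> List[RFFrame]:
        return self.frames[1:]


def simulate_acquisition(
    array: ArrayGeometry,
    scene: ScattererField,
    config: ReconstructionConfig = ReconstructionConfig(),
    seed: int = 0,
    opts: Optional[SimOptions] = None,
) -> AcquisitionResult:
    """Run the full excitation sequence over a scene.

    Sequence: a focused mock *therapy* burst (logged, no frame), a focused
    short *visualization* burst, then one steered plane wave per configured
    angle for B-mode formation.  All frames share the array, sampling rate
    and scene; per-frame noise seeds are spawned deterministically from
    ``seed``.
    """
    if opts is None:
        opts = SimOptions(
            spreading=config.spreading,
            directivity=config.directivity,
            noise_rms=config.noise_rms,
        )
    vis_pulse = make_pulse(config.vis_cycles, array.f0, array.fs)
    therapy_pulse = make_pulse(config.therapy_cycles, array.f0, array.fs)
    focus_tx = focused_delays(array, config.focus)

    # record long enough that the configured imaging depth range is fully
    # inside the window for every receive path (deep edge, edge elements)
    z_deep = float(config.depth_range[1])

    def _min_record(tx: TransmitEvent) -> float:
        return (
            float(tx.delays.max())
            + (z_deep + float(np.hypot(z_deep, array.aperture))) / array.c
            + vis_pulse.duration
        )

    noise_seeds = np.random.SeedSequence(seed).generate_state(len(config.angles_deg) + 1)
    log: List[dict] = [
        {
            "event": "therapy_burst",
            "kind": "focused",
            "focus": tuple(config.focus),
            "n_cycles": therapy_pulse.n_cycles,
            "duration_s": therapy_pulse.duration,
            "produces_frame": False,
        }
    ]
    frames: List[RFFrame] = []

    frames.append(
        simulate_rf(
            array, focus_tx, vis_pulse, scene, opts,
            seed=int(noise_seeds[0]), min_record_time=_min_record(focus_tx),
        )
    )
    log.append(
        {
            "event": "visualization_burst",
            "kind": "focused",
            "focus": tuple(config.focus),
            "n_cycles": vis_pulse.n_cycles,
            "produces_frame": True,
        }
    )
    for i, ang in enumerate(config.angles_deg):
        tx = plane_wave_delays(array, np.deg2rad(ang))
        frames.append(
            simulate_rf(
                array, tx, vis_pulse, scene, opts,
                seed=int(noise_seeds[i + 1]), min_record_time=_min_record(tx),
            )
        )
        log.append(
            {
                "event": "plane_wave",
                "kind": "plane_wave",
                "angle_deg": float(ang),
                "produces_frame": True,
            }
        )
    return AcquisitionResult(
        frames=frames, log=log, array=array, pulse=vis_pulse, config=config, seed=int(seed)
    )
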