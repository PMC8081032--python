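"""Seeded synthetic scatterer scenes: speckle backgrounds, circular contrast
targets, point/wire targets.

A scene is a discrete realization of the medium's scattering function: a
cloud of point scatterers with random positions and zero-mean Gaussian
reflectivities.  Fully developed speckle requires many scatterers per
resolution cell; the default background density is 15 scatterers per -6 dB
resolution cell (cell = n_cycles*lambda/2 axially x lambda*f_number
laterally).  A disk region with echogenicity offset g dB multiplies the
amplitude scale of the scatterers inside it by 10^(g/20), so the local
backscattered *intensity* is offset by g dB.  Point and wire targets are
single strong scatterers (default 40 dB above the background scale).

Scene regeneration is bit-identical for a given (spec, seed) pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "Disk",
    "PointTarget",
    "SceneSpec",
    "ScattererField",
    "build_scene",
    "preset_scene",
    "PRESET_NAMES",
]

#: region label of background scatterers; disk i gets label i+1, point
#: target j gets label POINT_LABEL_BASE + j
POINT_LABEL_BASE = 1000


@dataclass(frozen=True)
class Disk:
    """Circular contrast region with an echogenicity offset in dB."""

    center: Tuple[float, float]  # (x, z) m
    radius: float  # m
    offset_db: float


@dataclass(frozen=True)
class PointTarget:
    """A single strong scatterer (wire / nylon filament cross-section)."""

    x: float
    z: float
    level_db: float = 40.0  # amplitude above the background scale


@dataclass(frozen=True)
class SceneSpec:
    """Declarative scene description.

    ``density`` is in scatterers per -6 dB resolution cell; the cell size is
    derived from ``c``, ``f0``, ``n_cycles`` (axial) and ``rx_f_number``
    (lateral).  Set ``background=False`` for water scenes (no speckle).
    """

    x_span: Tuple[float, float] = (-5e-3, 5e-3)
    z_span: Tuple[float, float] = (26e-3, 34e-3)
    background: bool = True
    density: float = 15.0
    regions: Tuple[Disk, ...] = ()
    points: Tuple[PointTarget, ...] = ()
    c: float = 1540.0
    f0: float = 5e6
    n_cycles: int = 2
    rx_f_number: float = 1.0

    @property
    def wavelength(self) -> float:
        return self.c / self.f0

    @property
    def cell_area(self) -> float:
        """-6 dB resolution cell area (m^2): (n_cycles*lambda/2) x (lambda*f#)."""
        wl = self.wavelength
        return (self.n_cycles * wl / 2.0) * (wl * self.rx_f_number)

    @property
    def area(self) -> float:
        return (self.x_span[1] - self.x_span[0]) * (self.z_span[1] - self.z_span[0])

    @property
    def n_background(self) -> int:
        if not self.background:
            return 0
        return int(round(self.density * self.area / self.cell_area))


@dataclass(frozen=True)
class ScattererField:
    """Discrete scatterer realization: positions, reflectivities, labels."""

    x: np.ndarray
    z: np.ndarray
    amplitude: np.ndarray
    labels: np.ndarray  # int32: 0 background, i+1 disk i, 1000+j point j
    seed: int
    c: float = 1540.0

    def __len__(self) -> int:
        return self.x.size

    def scaled(self, factor: float) -> "ScattererField":
        """Same geometry with every amplitude multiplied by ``factor``."""
        return ScattererField(
            self.x, self.z, self.amplitude * factor, self.labels, self.seed, self.c
        )


def build_scene(spec: SceneSpec, seed: int) -> ScattererField:
    """Draw a deterministic scatterer field realizing ``spec``.

    Background positions are uniform over the field extent and reflectivities
    standard normal; disk regions rescale the amplitudes of the scatterers
    inside them by ``10**(offset_db/20)``.  The same (spec, seed) pair always
    regenerates a bit-identical field.
    """
    if spec.background and not spec.density > 0:
        raise ValueError("background scatterer density must be positive")
    for z0 in (spec.z_span[0], spec.z_span[1]):
        if not z0 > 0:
            raise ValueError("scene depth span must be strictly positive")

    rng = np.random.default_rng(seed)
    n_bg = spec.n_background
    x = rng.uniform(spec.x_span[0], spec.x_span[1], n_bg)
    z = rng.uniform(spec.z_span[0], spec.z_span[1], n_bg)
    amp = rng.standard_normal(n_bg)
    labels = np.zeros(n_bg, dtype=np.int32)

    for i, disk in enumerate(spec.regions):
        inside = (x - disk.center[0]) ** 2 + (z - disk.center[1]) ** 2 <= disk.radius**2
        amp[inside] *= 10.0 ** (disk.offset_db / 20.0)
        labels[inside] = i + 1

    if spec.points:
        px = np.array([p.x for p in spec.points], dtype=float)
        pz = np.array([p.z for p in spec.points], dtype=float)
        pa = np.array([10.0 ** (p.level_db / 20.0) for p in spec.points])
        pl = POINT_LABEL_BASE + np.arange(len(spec.points), dtype=np.int32)
        x = np.concatenate([x, px])
        z = np.concatenate([z, pz])
        amp = np.concatenate([amp, pa])
        labels = np.concatenate([labels, pl])

    if not np.all(np.isfinite(amp)):
        raise ValueError("scene produced non-finite amplitudes")
    return ScattererField(x, z, amp, labels, int(seed), spec.c)


def preset_scene(name: str, **overrides) -> SceneSpec:
    """Named scene presets emulating the studied targets.

    ``homogeneous``      uniform speckle phantom region
    ``hyperechoic_disk`` +15 dB circular contrast target at the focus
    ``hypoechoic_disk``  -15 dB circular contrast target at the focus
    ``contrast_p6`` / ``contrast_m6``  +-6 dB contrast targets
    ``point_line``       a lateral line of strong point targets in speckle
    ``wire_water``       a single wire target in degassed water (c = 1480,
                         no background speckle)

    Keyword overrides replace any :class:`SceneSpec` field.
    """
    focus_disk = dict(center=(0.0, 30e-3), radius=2.5e-3)
    presets = {
        "homogeneous": SceneSpec(),
        "hyperechoic_disk": SceneSpec(regions=(Disk(offset_db=15.0, **focus_disk),)),
        "hypoechoic_disk": SceneSpec(regions=(Disk(offset_db=-15.0, **focus_disk),)),
        "contrast_p6": SceneSpec(regions=(Disk(offset_db=6.0, **focus_disk),)),
        "contrast_m6": SceneSpec(regions=(Disk(offset_db=-6.0, **focus_disk),)),
        "point_line": SceneSpec(
            z_span=(25e-3, 33e-3),
            points=tuple(
                PointTarget(x=xi, z=29e-3) for xi in np.arange(-4e-3, 4.1e-3, 2e-3)
            ),
        ),
        "wire_water": SceneSpec(
            x_span=(-6e-3, 6e-3),
            z_span=(23e-3, 31e-3),
            background=False,
            points=(PointTarget(x=0.0, z=27e-3),),
            c=1480.0,
        ),
    }
    if name not in presets:
        raise KeyError(f"unknown scene preset {name!r}; options: {sorted(presets)}")
    spec = presets[name]
    if overrides:
        from dataclasses import replace

        spec = replace(spec, **overrides)
    return spec


PRESET_NAMES = (
    "homogeneous",
    "hyperechoic_disk",
    "hypoechoic_disk",
    "contrast_p6",
    "contrast_m6",
    "point_line",
    "wire_water",
)
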