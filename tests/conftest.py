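"""Shared fixtures: session-scoped simulated acquisitions and reconstructions.

The heavy fixtures run the full 128-element, 8-transmit pipeline over
speckle scenes (~10^4 scatterers) once per session and are shared by the
unit and acceptance tests.  All seeds are fixed constants.
"""

import numpy as np
import pytest

import fusviz as fv

DEMO_SEED = 101
TARGET_SEED = 21
EQUALIZATION_SEED = 11
WIRE_SEED = 5
BASELINE_SEEDS = (101, 102, 103, 104, 105)

#: +15 dB contrast disk centered at the FUS focus (paper-style targeting)
FOCUS_DISK = fv.Disk(center=(0.0, 30e-3), radius=2.5e-3, offset_db=15.0)


@pytest.fixture(scope="session")
def array128():
    return fv.make_array()


@pytest.fixture(scope="session")
def pulse2():
    return fv.make_pulse(2)


@pytest.fixture(scope="session")
def demo_run(array128):
    """Homogeneous speckle phantom, default config: (acquisition, recon)."""
    cfg = fv.ReconstructionConfig()
    scene = fv.build_scene(fv.preset_scene("homogeneous"), DEMO_SEED)
    acq = fv.simulate_acquisition(array128, scene, cfg, seed=DEMO_SEED)
    return acq, fv.reconstruct_acquisition(acq)


@pytest.fixture(scope="session")
def point_acq(array128):
    """A single unit scatterer at the transmit focus, no background."""
    spec = fv.SceneSpec(
        background=False,
        points=(fv.PointTarget(0.0, 30e-3, level_db=0.0),),
        x_span=(-5e-3, 5e-3),
        z_span=(27e-3, 33e-3),
    )
    cfg = fv.ReconstructionConfig(depth_range=(27e-3, 33e-3))
    scene = fv.build_scene(spec, 1)
    return fv.simulate_acquisition(array128, scene, cfg, seed=1)


@pytest.fixture(scope="session")
def point_recon(point_acq):
    return fv.reconstruct_acquisition(point_acq)


@pytest.fixture(scope="session")
def wire_recon():
    """Wire target in degassed water (c = 1480), small sensor noise so the
    B-mode has a finite floor for ungated normalization."""
    array = fv.make_array(c=1480.0)
    scene = fv.build_scene(fv.preset_scene("wire_water"), WIRE_SEED)
    cfg = fv.ReconstructionConfig(
        focus=(0.0, 27e-3), depth_range=(23e-3, 31e-3), noise_rms=1.0
    )
    acq = fv.simulate_acquisition(array, scene, cfg, seed=WIRE_SEED)
    return fv.reconstruct_acquisition(acq)


@pytest.fixture(scope="session")
def equalization_pair(array128):
    """Two scenes sharing one scatterer geometry: uniform amplitudes vs a
    +15 dB disk at the focus.  Returns (recon_uniform, recon_disk)."""
    cfg = fv.ReconstructionConfig(depth_range=(25e-3, 35e-3))
    base = dict(x_span=(-5e-3, 5e-3), z_span=(25e-3, 35e-3))
    spec_a = fv.SceneSpec(**base)
    spec_b = fv.SceneSpec(regions=(FOCUS_DISK,), **base)
    scene_a = fv.build_scene(spec_a, EQUALIZATION_SEED)
    scene_b = fv.build_scene(spec_b, EQUALIZATION_SEED)
    recon_a = fv.reconstruct_acquisition(
        fv.simulate_acquisition(array128, scene_a, cfg, seed=EQUALIZATION_SEED)
    )
    recon_b = fv.reconstruct_acquisition(
        fv.simulate_acquisition(array128, scene_b, cfg, seed=EQUALIZATION_SEED)
    )
    return recon_a, recon_b


@pytest.fixture(scope="session")
def mse_ensemble(array128, demo_run):
    """A +15 dB contrast-target reconstruction plus five homogeneous
    baseline reconstructions (distinct speckle seeds, same sequence)."""
    cfg = fv.ReconstructionConfig()
    target_scene = fv.build_scene(fv.preset_scene("hyperechoic_disk"), TARGET_SEED)
    target = fv.reconstruct_acquisition(
        fv.simulate_acquisition(array128, target_scene, cfg, seed=TARGET_SEED)
    )
    baselines = [demo_run[1]]  # demo fixture is the first homogeneous baseline
    for s in BASELINE_SEEDS[1:]:
        scene = fv.build_scene(fv.preset_scene("homogeneous"), s)
        baselines.append(
            fv.reconstruct_acquisition(fv.simulate_acquisition(array128, scene, cfg, seed=s))
        )
    return target, baselines
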