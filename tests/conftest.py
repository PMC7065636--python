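import numpy as np
import pytest

from hsoct import recon, synth


@pytest.fixture(scope="session")
def noise_free_spectrometer():
    return synth.default_spectrometer(read_noise_sd=0.0)


@pytest.fixture(scope="session")
def single_reflector_stack(noise_free_spectrometer):
    """Noise-free single-reflector B-scan reconstructed with defaults."""
    scene = synth.make_single_reflector_scene(z_um=100.0, lateral_extent_um=24.0)
    raw = synth.simulate_bscan(
        scene, spectrometer=noise_free_spectrometer, n_ascans=16, repeats=1, seed=1
    )
    stack = recon.reconstruct_stack(raw, register=False)
    return scene, raw, stack


@pytest.fixture(scope="session")
def phantom_analysis():
    """10 mg/mL phantom simulated, reconstructed and analyzed end to end."""
    from hsoct import dfm

    scene = synth.make_phantom_scene(10.0, seed=5)
    raw = synth.simulate_bscan(scene, n_ascans=128, repeats=3, seed=5)
    stack = recon.reconstruct_stack(raw)
    res = dfm.analyze_stack(stack)
    return scene, raw, stack, res


def reflector_column(scene, raw) -> int:
    """Image column of a single-reflector scene's scatterer."""
    return int(round(float(scene.x_um[0]) / raw.lateral_pitch_um))


def granule_image_coords(scene, stack, lateral_pitch_um):
    """Ground-truth granule positions in image pixel coordinates."""
    gmask = scene.mask("granule")
    rows = np.round(
        scene.z_um[gmask] * scene.n_group / stack.pitch_z_um
    ).astype(int)
    cols = np.round(scene.x_um[gmask] / lateral_pitch_um).astype(int)
    return rows, cols
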