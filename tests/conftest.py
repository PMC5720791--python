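import numpy as np
import pytest

from xhclust import SceneSpec, build_mask, cube_to_matrix, crop_bands, make_wound_cube, savgol_smooth


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_cube():
    """A tiny 4x4x3 cube with fixed values for I/O round trips."""
    from xhclust import SpectralCube

    rng = np.random.default_rng(7)
    values = rng.uniform(0, 1, size=(4, 4, 3)).astype(np.float32)
    return SpectralCube(values, [500.0, 600.0, 700.0])


def preprocess_scene(cube):
    """Standard chain used across tests: mask, flatten, smooth, crop."""
    mask = build_mask(cube)
    return crop_bands(savgol_smooth(cube_to_matrix(cube, mask))), mask


@pytest.fixture(scope="session")
def separated_scene():
    """One well-separated synthetic scene plus its preprocessed matrix."""
    cube, truth = make_wound_cube(SceneSpec(seed=11))
    matrix, mask = preprocess_scene(cube)
    return {"cube": cube, "truth": truth, "matrix": matrix, "mask": mask}
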