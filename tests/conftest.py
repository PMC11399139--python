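import numpy as np
import pytest

from mptet.synthetic import TriangleParams, generate_triangle_scene, write_scene_to_dir


@pytest.fixture(scope="session")
def noisefree_scene():
    """A 224x224 noise-free triangle scene with known truth."""
    params = TriangleParams(n_rows=224, n_cols=224, ts_noise_sd_K=0.0, seed=11)
    return generate_triangle_scene(params)


@pytest.fixture(scope="session")
def noisy_scene():
    """A 224x224 scene at the standard 0.5 K temperature noise."""
    params = TriangleParams(n_rows=224, n_cols=224, ts_noise_sd_K=0.5, seed=12)
    return generate_triangle_scene(params)


@pytest.fixture()
def scene_on_disk(tmp_path):
    """A small synthetic scene written as GeoTIFF bands + MTL, for the reader path."""
    params = TriangleParams(n_rows=60, n_cols=60, ts_noise_sd_K=0.3, seed=7)
    scene, truth = generate_triangle_scene(params)
    paths = write_scene_to_dir(scene, tmp_path / "scene")
    return scene, truth, paths


@pytest.fixture()
def rng():
    return np.random.default_rng(20230315)
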