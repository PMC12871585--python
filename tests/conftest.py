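import numpy as np
import pytest

from conewell import gridmap, scene_sim


@pytest.fixture(scope="session")
def layout():
    return gridmap.PlateLayout(pixel_size_um=2.0)


@pytest.fixture(scope="session")
def noiseless_scene():
    """10x10 noiseless scene with planted drift; loading at lambda=1."""
    cfg = scene_sim.SceneConfig(
        grid_rows=10,
        grid_cols=10,
        n_timepoints=4,
        channels=("BF",),
        loading_density=1.0,
        drift_px_per_t=(2, 3),
        noise=scene_sim.NoiseModel(sigma=0.0),
        seed=41,
    )
    return scene_sim.render_scene(cfg)


@pytest.fixture(scope="session")
def noisy_scene():
    """Same scene with Gaussian noise at 10% of the ring contrast."""
    cfg = scene_sim.SceneConfig(
        grid_rows=10,
        grid_cols=10,
        n_timepoints=4,
        channels=("BF",),
        loading_density=1.0,
        drift_px_per_t=(2, 3),
        noise=scene_sim.NoiseModel(sigma=8.0),  # ring_depth is 80
        seed=41,
    )
    return scene_sim.render_scene(cfg)


@pytest.fixture(scope="session")
def secretion_scene():
    """Small co-culture scene with planted positives and cross-talk arcs."""
    cfg = scene_sim.preset("peptide_pulsed", grid_rows=8, grid_cols=8, seed=17)
    return scene_sim.render_scene(cfg)


def truth_centers(truth) -> np.ndarray:
    return truth.table[["center_y", "center_x"]].to_numpy()
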