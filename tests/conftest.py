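import numpy as np
import pytest

from patchstat import GeneratorConfig, generate_crazy_quilt, generate_regular_quilt, load_template


def random_simple_polygon(rng, n_vertices=12, radius=1.0):
    """Star-shaped polygon around a random centre: simple by construction."""
    from shapely.geometry import Polygon

    while True:
        angles = np.sort(rng.uniform(0, 2 * np.pi, n_vertices))
        if np.min(np.diff(angles)) < 1e-2:
            continue
        radii = rng.uniform(0.3 * radius, radius, n_vertices)
        cx, cy = rng.uniform(2, 8, 2)
        verts = [
            (cx + r * np.cos(a), cy + r * np.sin(a)) for r, a in zip(radii, angles)
        ]
        poly = Polygon(verts)
        if poly.is_valid and poly.is_simple and poly.area > 0.05:
            return verts


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20231)


@pytest.fixture(scope="session")
def small_crazy_quilt():
    return generate_crazy_quilt((60, 50), GeneratorConfig(seed=2, target_n=90))


@pytest.fixture(scope="session")
def small_regular_quilt():
    return generate_regular_quilt(
        load_template("four_patch"), 5, 6, GeneratorConfig(seed=2)
    )
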