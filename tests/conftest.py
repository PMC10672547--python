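import numpy as np
import pytest
import trimesh

# canonical unit cube: 8 vertices, 12 outward-oriented faces
CUBE_VERTICES = np.array([
    [0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0],
    [0, 0, 1], [1, 0, 1], [1, 1, 1], [0, 1, 1],
], dtype=float)
CUBE_FACES = np.array([
    [0, 3, 1], [1, 3, 2],   # bottom (z=0)
    [4, 5, 7], [5, 6, 7],   # top (z=1)
    [0, 1, 4], [1, 5, 4],   # front (y=0)
    [2, 3, 6], [3, 7, 6],   # back (y=1)
    [0, 4, 3], [3, 4, 7],   # left (x=0)
    [1, 2, 5], [2, 6, 5],   # right (x=1)
])


@pytest.fixture
def unit_cube() -> trimesh.Trimesh:
    return trimesh.Trimesh(vertices=CUBE_VERTICES.copy(), faces=CUBE_FACES.copy(),
                           process=False)


@pytest.fixture
def icosphere_r10() -> trimesh.Trimesh:
    return trimesh.creation.icosphere(subdivisions=4, radius=10.0)


def digitized_ball(radius: int, pad: int = 3) -> np.ndarray:
    """Boolean grid of a centred solid sphere of the given voxel radius."""
    n = 2 * radius + 2 * pad + 1
    centre = (n - 1) / 2
    idx = np.indices((n, n, n)) - centre
    return (idx ** 2).sum(axis=0) <= radius ** 2
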