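import numpy as np
import pytest

from csdsi.phantom import PhantomConfig, noise_free_attenuation
from csdsi.qspace import CartesianQGrid, ProtocolMeta, build_grid


@pytest.fixture(scope="session")
def grid() -> CartesianQGrid:
    return build_grid(5, 6800.0)


@pytest.fixture(scope="session")
def meta() -> ProtocolMeta:
    return ProtocolMeta()


def attenuation_cube(config: PhantomConfig, grid: CartesianQGrid) -> np.ndarray:
    """Noise-free E(q) on the full cubic grid (zeros outside the sphere)."""
    n = 2 * grid.radius + 1
    pts = grid.points
    bvals = np.array([grid.b_of(p) for p in pts])
    norms = np.linalg.norm(pts, axis=1, keepdims=True)
    dirs = np.where(bvals[:, None] > 0, pts / np.maximum(norms, 1e-12), 0.0)
    E_vals = noise_free_attenuation(config, bvals, dirs)
    E = np.zeros((n, n, n))
    r = grid.radius
    for p, e in zip(pts, E_vals):
        E[p[0] + r, p[1] + r, p[2] + r] = e
    return E
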