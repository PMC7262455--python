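import numpy as np
import pytest

import flexscatter as fs


@pytest.fixture(scope="session")
def qgrid_small():
    return fs.default_qgrid(150)


@pytest.fixture(scope="session")
def lattice_sphere_beads():
    """~2000 beads on a cubic lattice filling a sphere of radius 50 A."""
    R, target = 50.0, 2000
    a = (4.0 / 3.0 * np.pi * R**3 / target) ** (1.0 / 3.0)
    m = int(np.ceil(R / a))
    g = np.arange(-m, m + 1) * a
    X, Y, Z = np.meshgrid(g, g, g, indexing="ij")
    pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    pts = pts[np.einsum("ij,ij->i", pts, pts) <= R * R]
    return fs.BeadModel(positions=pts)


@pytest.fixture(scope="session")
def small_pool():
    return fs.generate_pool(30, seed=2)


@pytest.fixture(scope="session")
def one_conformer():
    return fs.assemble_conformer(fs.default_layout(), seed=42)
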