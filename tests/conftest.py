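import numpy as np
import pytest

import tangmorph as tm


def circle_points(n=512, r=1.0, center=(0.0, 0.0)):
    t = np.linspace(0.0, 2 * np.pi, n, endpoint=False)
    return np.column_stack([center[0] + r * np.cos(t), center[1] + r * np.sin(t)])


def ellipse_points(n=512, a=2.0, b=1.0):
    t = np.linspace(0.0, 2 * np.pi, n, endpoint=False)
    return np.column_stack([a * np.cos(t), b * np.sin(t)])


def square_points(n_per_side=128, side=1.0):
    s = np.linspace(0.0, side, n_per_side, endpoint=False)
    z = np.zeros_like(s)
    return np.vstack(
        [
            np.column_stack([s, z]),
            np.column_stack([z + side, s]),
            np.column_stack([side - s, z + side]),
            np.column_stack([z, side - s]),
        ]
    )


@pytest.fixture
def circle_outline():
    return tm.Outline("circle", circle_points())


@pytest.fixture
def ellipse_outline():
    return tm.Outline("ellipse", ellipse_points())


@pytest.fixture
def square_outline():
    return tm.Outline("square", square_points())


@pytest.fixture(scope="session")
def small_assemblage():
    """60 synthetic specimens, enough structure for unit tests, fast."""
    spec = tm.AssemblageSpec(n=60, seed=7)
    return tm.generate_assemblage(spec)


@pytest.fixture(scope="session")
def assemblage400():
    """A full-size mixed reduction assemblage at the default study conditions."""
    spec = tm.AssemblageSpec(n=400, seed=11)
    return tm.generate_assemblage(spec)


@pytest.fixture(scope="session")
def shape_space400(assemblage400):
    outlines, _, _ = assemblage400
    coeffs = [tm.standardized_coefficients(o) for o in outlines]
    return tm.fit_pca(tm.coefficient_matrix(coeffs))
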