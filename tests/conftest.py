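"""Shared fixtures: small minimized configurations reused across test modules."""

import numpy as np
import pytest

import sphepi


def icosahedron_positions() -> np.ndarray:
    phi = (1 + np.sqrt(5)) / 2
    pts = []
    for a in (-1.0, 1.0):
        for b in (-phi, phi):
            pts += [(0, a, b), (a, b, 0), (b, 0, a)]
    pts = np.array(pts)
    return pts / np.linalg.norm(pts, axis=1)[:, None]


def tetrahedron_positions() -> np.ndarray:
    pts = np.array([(1, 1, 1), (1, -1, -1), (-1, 1, -1), (-1, -1, 1)], dtype=float)
    return pts / np.sqrt(3)


@pytest.fixture(scope="session")
def icosahedron() -> np.ndarray:
    return icosahedron_positions()


@pytest.fixture(scope="session")
def tetrahedron() -> np.ndarray:
    return tetrahedron_positions()


@pytest.fixture(scope="session")
def minimized_small():
    """Minimized heterogeneous packing (N=60, sigma=0.1, alpha=12, seed=0)."""
    return sphepi.minimized_configuration(60, 0.1, 12.0, seed=0)


@pytest.fixture(scope="session")
def minimized_medium():
    """Minimized heterogeneous packing (N=150, sigma=0.1, alpha=12, seed=1)."""
    return sphepi.minimized_configuration(150, 0.1, 12.0, seed=1)
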