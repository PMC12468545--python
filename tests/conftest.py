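import numpy as np
import pytest

import ihcnorm as ih


def angle_deg(a: np.ndarray, b: np.ndarray) -> float:
    """Angle in degrees between two vectors."""
    a = np.asarray(a, float) / np.linalg.norm(a)
    b = np.asarray(b, float) / np.linalg.norm(b)
    return float(np.degrees(np.arccos(np.clip(a @ b, -1.0, 1.0))))


def basis_error_deg(V: np.ndarray, V_true: np.ndarray) -> float:
    """Largest per-column angular error between two ordered stain bases."""
    return max(angle_deg(V[:, j], V_true[:, j]) for j in range(V_true.shape[1]))


@pytest.fixture(scope="session")
def default_scene():
    """The standard synthetic scene (256x256, OD noise 0.01)."""
    return ih.make_scene()


@pytest.fixture(scope="session")
def noiseless_scene():
    return ih.make_scene(ih.SynthConfig(noise_sigma=0.0))


@pytest.fixture(scope="session")
def small_scene():
    """A quicker 128x128 scene for the heavier end-to-end tests."""
    return ih.make_scene(ih.SynthConfig(height=128, width=128, n_nuclei=6, seed=1))
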