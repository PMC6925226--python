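import numpy as np
import pytest

from capsgeom import assembly as asm
from capsgeom import synthetic as syn

#: fixed seed for every stochastic fixture in the suite
SEED = 2019

#: closed-form interface counts per shell class
INTERFACE_COUNTS = {"T1": 30, "T3": 90, "D5": 45, "D6": 54}
RING_FOLDS = {"T1": (12, 0), "T3": (12, 20), "D5": (12, 5), "D6": (12, 8)}
CHAIN_COUNTS = {"T1": 60, "T3": 180, "D5": 90, "D6": 108}


@pytest.fixture(scope="session")
def shells():
    """Noise-free synthetic shells plus manifests, one per class."""
    return {cls: syn.make_shell(syn.ShellRecipe.for_class(cls))
            for cls in syn.SHELL_CLASSES}


@pytest.fixture(scope="session")
def noisy_shells():
    """Shells with 0.3 A isotropic coordinate noise (fixed seed)."""
    return {cls: syn.make_shell(
        syn.ShellRecipe.for_class(cls, seed=SEED, noise_sigma=0.3))
        for cls in syn.SHELL_CLASSES}


@pytest.fixture(scope="session")
def analyzed(shells):
    """Detected rings and enumerated interfaces for the noise-free shells."""
    out = {}
    for cls, (model, manifest) in shells.items():
        axis = np.array([0.0, 0.0, 1.0]) if cls.startswith("D") else None
        rings = asm.detect_rings(model)
        interfaces = asm.enumerate_interfaces(model, rings, principal_axis=axis)
        out[cls] = (model, manifest, rings, interfaces)
    return out


def random_rotation(rng):
    """Uniform-ish random proper rotation from a random quaternion."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])
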