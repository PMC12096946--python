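import numpy as np
import pytest

from ccdimer.peptide import extended_chain, ideal_helix
from ccdimer.synthetic import (build_palb2_brca1_heterodimer,
                               build_palb2_homodimer, build_palb2_protomer)


@pytest.fixture(scope="session")
def helix20():
    """Ideal 20-residue poly-Ala alpha-helix."""
    return ideal_helix("A" * 20)


@pytest.fixture(scope="session")
def helix30():
    """Ideal 30-residue poly-Ala alpha-helix."""
    return ideal_helix("A" * 30)


@pytest.fixture(scope="session")
def extended20():
    """Fully extended 20-residue poly-Ala chain."""
    return extended_chain("A" * 20)


@pytest.fixture(scope="session")
def palb2_protomer():
    """Single PALB2 coiled-coil helix with full side chains."""
    return build_palb2_protomer()


@pytest.fixture(scope="session")
def palb2_homodimer():
    """Antiparallel PALB2 coiled-coil homodimer, full side chains."""
    return build_palb2_homodimer()


@pytest.fixture(scope="session")
def heterodimer():
    """PALB2 / synthetic BRCA1-like antiparallel heterodimer."""
    return build_palb2_brca1_heterodimer()


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform-ish random rotation matrix."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])
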