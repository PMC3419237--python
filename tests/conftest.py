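import numpy as np
import pytest

from rnrkit.epr_sim import (
    GTensor,
    SpectrometerSettings,
    SpinSystem,
    powder_spectrum,
    preset_spin_system,
)


@pytest.fixture(scope="session")
def xband():
    return SpectrometerSettings(frequency_GHz=9.67)


@pytest.fixture(scope="session")
def hf_band():
    return SpectrometerSettings(frequency_GHz=285.0)


@pytest.fixture(scope="session")
def isotropic_system():
    # tiny anisotropy keeps the ordered-tensor contract while behaving
    # as a single symmetric line
    return SpinSystem(GTensor(2.00501, 2.005, 2.00499), name="isotropic")


@pytest.fixture(scope="session")
def mouse_r2_xband_spectrum(xband):
    return powder_spectrum(preset_spin_system("mouse_R2"), xband)


def tree_path_distances(tree):
    """Leaf-to-leaf path-length matrix of a Bio.Phylo tree (test oracle)."""
    terminals = sorted(tree.get_terminals(), key=lambda t: t.name)
    labels = [t.name for t in terminals]
    n = len(labels)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = tree.distance(terminals[i], terminals[j])
            mat[i, j] = mat[j, i] = d
    return labels, mat
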