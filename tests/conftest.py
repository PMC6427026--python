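import numpy as np
import pytest

import fibrilmetrics as fm


@pytest.fixture(scope="session")
def arch_layer():
    """Small flat protomer layer shared by the helical tests."""
    return fm.generate_beta_arch_layer(12)


@pytest.fixture(scope="session")
def stack5(arch_layer):
    """Five-layer stack at the deposited symmetry (4.8 A, -0.58 deg)."""
    return fm.build_stack(arch_layer, fm.HelicalSymmetry(4.8, -0.58), 5)


@pytest.fixture(scope="session")
def phantom():
    """Shell phantom enclosing a 3 A void (analytic volume 113.1 A^3)."""
    return fm.generate_cavity_phantom(fm.PhantomSpec(void_radius=3.0))


@pytest.fixture(scope="session")
def phantom_cavities(phantom):
    """Cavities of the 3 A phantom at the default 0.5 A grid."""
    return fm.find_cavities(phantom, spacing=0.5)


@pytest.fixture
def strand_pair_models():
    """Two-strand CA models: parallel and with the second strand reversed."""
    ca_a = np.column_stack([np.arange(8) * 3.8, np.zeros(8), np.zeros(8)])
    ca_b = ca_a + np.array([0.0, 5.0, 0.0])
    res = list(range(16, 24)) + list(range(86, 94))
    parallel = fm.AtomicModel.from_arrays(np.vstack([ca_a, ca_b]), res_seq=res)
    flipped = fm.AtomicModel.from_arrays(np.vstack([ca_a, ca_b[::-1]]), res_seq=res)
    return parallel, flipped
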