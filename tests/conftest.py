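import numpy as np
import pytest

from tbion import RnaStructure, SolutionCondition, TbiConfig, generate_aform_helix


@pytest.fixture(scope="session")
def helix12():
    return generate_aform_helix(12)


@pytest.fixture(scope="session")
def helix2():
    return generate_aform_helix(2)


@pytest.fixture(scope="session")
def cond37():
    return SolutionCondition(temperature_celsius=37.0, c_na=0.1, c_mg=0.0)


@pytest.fixture()
def single_phosphate():
    """A lone phosphate group: one P atom of radius 2.1 A at the origin."""
    return RnaStructure(
        elements=["P"],
        atom_nt=np.array([1]),
        atom_xyz=np.array([[0.0, 0.0, 0.0]]),
        atom_radius=np.array([2.1]),
        phos_nt=np.array([1]),
        phos_xyz=np.array([[0.0, 0.0, 0.0]]),
        n_nucleotides=1,
    )


@pytest.fixture()
def two_phosphates():
    """Two bare phosphate spheres 12 A apart (a minimal 2-cell system)."""
    xyz = np.array([[0.0, 0.0, 0.0], [12.0, 0.0, 0.0]])
    return RnaStructure(
        elements=["P", "P"],
        atom_nt=np.array([1, 2]),
        atom_xyz=xyz,
        atom_radius=np.array([2.1, 2.1]),
        phos_nt=np.array([1, 2]),
        phos_xyz=xyz.copy(),
        n_nucleotides=2,
    )


@pytest.fixture(scope="session")
def coarse_config():
    """Coarse, fast numerics for small test systems."""
    return TbiConfig(grid_spacing=1.2, coarse_spacing=3.0, padding_debye=2.5,
                     padding_min=10.0, focus_margin=8.0, pb_tol=1e-6)
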