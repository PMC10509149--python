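import numpy as np
import pytest

from braggfricke import (
    CARBON,
    PMMA,
    PROTON,
    SUPER_FRICKE,
    BeamSpec,
    FibreArray,
    MaterialStack,
    bragg_elf_curve,
)


@pytest.fixture(scope="session")
def proton_stack():
    """64-MeV beamline geometry: 23.57 mm PMMA degrader + 10 mm cuvette."""
    return MaterialStack(
        ((PMMA, 23.57), (SUPER_FRICKE, 10.0)), sample_index=1
    )


@pytest.fixture(scope="session")
def carbon_stack():
    """1.14-GeV carbon geometry: 14 mm PMMA degrader + 10 mm cuvette."""
    return MaterialStack(((PMMA, 14.0), (SUPER_FRICKE, 10.0)), sample_index=1)


def proton_beam(current_nA=1.0):
    return BeamSpec(PROTON, 64.0, 0.3, current_nA * 1e-9, 8.0)


def carbon_beam(current_nA=0.1):
    return BeamSpec(CARBON, 1140.0, 0.0, current_nA * 1e-9, 8.0)


@pytest.fixture(scope="session")
def proton_profile(proton_stack):
    return bragg_elf_curve(proton_beam(), proton_stack)


@pytest.fixture(scope="session")
def carbon_profile(carbon_stack):
    return bragg_elf_curve(carbon_beam(), carbon_stack)


@pytest.fixture(scope="session")
def fibre_array():
    return FibreArray()


def fibre_truth_average(values, grid, fa):
    """Average a depth-gridded truth over each fibre interval (shallow->deep)."""
    out = np.empty(fa.n_fibres)
    for j, fibre in enumerate(fa.fibre_indices()):
        x0, x1 = fa.depth_interval(int(fibre))
        m = (grid >= x0) & (grid < x1)
        out[j] = values[m].mean() if m.any() else np.nan
    return out
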