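import numpy as np
import pytest

import rdscales as rd


@pytest.fixture(scope="session")
def reference_params() -> rd.KineticParams:
    return rd.KineticParams.reference()


@pytest.fixture(scope="session")
def reference_bundle() -> rd.RunBundle:
    """The reference radial-subdivision experiment, run once per session."""
    return rd.run_reference()


@pytest.fixture(scope="session")
def negative_control_bundle() -> rd.RunBundle:
    """Reference experiment with the inhibitor diffusivity lowered to the
    activator's (no differential diffusion, hence no lateral inhibition)."""
    p = rd.KineticParams.reference().replace(D_v=rd.KineticParams.reference().D_u)
    return rd.run_reference({"params": p.to_dict()})


def brute_force_disc_cells(lattice: rd.LatticeSpec, centre, R):
    """Independent enumeration of cells whose centres fall inside a disc."""
    cells = []
    for i in range(lattice.n):
        for j in range(lattice.n):
            x = (j + 0.5) * lattice.h
            y = (i + 0.5) * lattice.h
            if (x - centre[0]) ** 2 + (y - centre[1]) ** 2 < R * R:
                cells.append((i, j))
    return cells


@pytest.fixture
def small_lattice() -> rd.LatticeSpec:
    return rd.LatticeSpec(L=10.0, n=10)
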