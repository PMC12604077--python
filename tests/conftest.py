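import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from spinfit import AcquisitionGrid, default_library, make_timing, simulate_basis


@pytest.fixture(scope="session")
def lib():
    return default_library()


@pytest.fixture(scope="session")
def grid():
    """Desk-scale grid: 2500 Hz / 4096 points covers 0-10 ppm at 3T."""
    return AcquisitionGrid(sweep_width_hz=2500.0, n_points=4096)


@pytest.fixture(scope="session")
def small_basis_te35(lib, grid):
    """Reduced five-metabolite PRESS TE-35 basis reused across fit tests."""
    return simulate_basis(
        lib, ["NAA", "Cr", "mI", "Gly", "Lac"], make_timing("press", 35.0), grid, 8.0
    )


@pytest.fixture(scope="session")
def mi_gly_basis_factory(lib, grid):
    def make(te_ms, kind="press", linewidth_hz=8.0):
        return simulate_basis(
            lib, ["mI", "Gly"], make_timing(kind, te_ms), grid, linewidth_hz
        )

    return make
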