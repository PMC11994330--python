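import numpy as np
import pytest

from fetalsurf.mesh import TriangleMesh, make_icosphere
from fetalsurf.simulate import SimulationConfig


@pytest.fixture(scope="session")
def unit_icosphere_s5() -> TriangleMesh:
    return make_icosphere(5, 1.0)


@pytest.fixture(scope="session")
def tetrahedron() -> TriangleMesh:
    v = np.array(
        [[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], dtype=float
    )
    f = np.array([[0, 1, 2], [0, 3, 1], [0, 2, 3], [1, 3, 2]])
    return TriangleMesh(v, f)


@pytest.fixture(scope="session")
def small_cohort_config() -> SimulationConfig:
    """Reduced cohort for fast pipeline tests: 8 regions, 4 affected."""
    regions = tuple(
        f"{h}_{n}"
        for h in ("L", "R")
        for n in ("precentral", "postcentral", "lingual", "superiortemporal")
    )
    return SimulationConfig(
        regions=regions,
        affected_regions=regions[:4],
        metrics=("surface_area",),
        n_control_subjects=60,
        n_chd_subjects=40,
        fraction_longitudinal_control=0.3,
        fraction_longitudinal_chd=0.5,
        fraction_hlhs_tga=0.4,
        n_followup_chd=25,
        n_followup_control=18,
        seed=0,
    )
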