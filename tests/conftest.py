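import numpy as np
import pytest

from rhinoflow.airspace import extract_airspace
from rhinoflow.phantom import PhantomSpec, build_phantom_truth, desk_scale_config
from rhinoflow.pipeline import StudyConfig, run_study


def study_spec(**overrides) -> PhantomSpec:
    """The desk-scale phantom used across the unit tests (48^3)."""
    kw = dict(grid_shape=(48, 48, 48), spacing=2.667, nostril_radius_mm=12.0,
              seed=1)
    kw.update(overrides)
    return PhantomSpec(**kw)


@pytest.fixture(scope="session")
def truth48():
    return build_phantom_truth(study_spec(constriction_side="right"))


@pytest.fixture(scope="session")
def domain48(truth48):
    spec = truth48.spec
    return extract_airspace(truth48.volume, sphere_diam_mm=spec.sphere_diam_mm,
                            cuboid_dims_mm=spec.cuboid_dims_mm, sdf=truth48.sdf)


@pytest.fixture(scope="session")
def lattice_cfg48(truth48):
    return desk_scale_config(truth48.spec)


@pytest.fixture(scope="session")
def study_result():
    """The five-subject synthetic comparison study (runs once per session)."""
    return run_study(StudyConfig(seed=1))
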