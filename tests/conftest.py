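import numpy as np
import pytest

import tavrsim as tv


def make_cylinder_params(diameter: float = 25.0, calcium=None) -> tv.RootParams:
    """Degenerate anatomy: all five levels at the same diameter."""
    return tv.RootParams(
        lvot_diameter=diameter,
        annulus_diameter=diameter,
        sinus_diameter=diameter,
        stj_diameter=diameter,
        ascending_diameter=diameter,
        calcium_volumes=calcium or {},
    )


@pytest.fixture(scope="session")
def reference_params() -> tv.RootParams:
    return tv.reference_root_params()


@pytest.fixture(scope="session")
def reference_root(reference_params) -> tv.AorticRootModel:
    """Cohort-mean anatomy with calcium, default mesh."""
    root = tv.generate_root(reference_params)
    return tv.place_calcium(root, reference_params, seed=0)


@pytest.fixture(scope="session")
def cylinder_root() -> tv.AorticRootModel:
    return tv.generate_root(make_cylinder_params())


@pytest.fixture(scope="session")
def device29() -> tv.THVDevice:
    return tv.get_device("EvolutPRO-29")


@pytest.fixture(scope="session")
def reference_deployment(reference_root, device29) -> tv.DeploymentResults:
    return tv.deploy(reference_root, device29)
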