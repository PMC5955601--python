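import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import fieldpol as fp

settings.register_profile(
    "default", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

LAMBDA_UM = 500.0
TAU_MS = 40.0


def to_norm(amp_mV_per_Vm, lambda_um=LAMBDA_UM):
    """mV/(V/m) -> V/(V/lambda) for a cable with space constant lambda."""
    return np.asarray(amp_mV_per_Vm) * 1000.0 / lambda_um


@pytest.fixture(scope="session")
def cable():
    """Passive straight cable, L = 1 lambda, tau = 40 ms (model, axis)."""
    return fp.straight_cable_model(fp.CableSpec())


@pytest.fixture(scope="session")
def pyramidal():
    """Surrogate pyramidal cell: (points, axis, graph)."""
    pts = fp.make_surrogate_pyramidal(fp.SurrogatePyramidalSpec(seed=1))
    axis = fp.compute_field_axis(pts)
    graph = fp.build_compartments(pts, 10.0)
    return pts, axis, graph
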