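import pytest

from arousalctl import (
    CircuitSpec,
    KernelSpec,
    RegulatorSpec,
    TimeGrid,
)


@pytest.fixture
def grid():
    """Default grid: horizon 100 t.u. at dt = 0.01."""
    return TimeGrid.from_horizon(100.0, dt=0.01)


@pytest.fixture
def short_grid():
    return TimeGrid.from_horizon(10.0, dt=0.01)


@pytest.fixture
def integral_circuit(grid):
    """Basic loop with an integrator whose window exceeds the horizon."""
    reg = RegulatorSpec("window_integral", k=1.0, w=grid.duration + 1.0)
    return CircuitSpec("basic", regulator=reg)


@pytest.fixture
def feedforward_integral_circuit(grid):
    reg = RegulatorSpec("window_integral", k=1.0, w=grid.duration + 1.0)
    return CircuitSpec("feedforward", regulator=reg)


def make_regulator(kind: str, k: float = 1.0, **overrides) -> RegulatorSpec:
    """Regulator of any kind with canonical test parameters."""
    params = {}
    if kind == "window_integral":
        params["w"] = overrides.pop("w", 5.0)
    elif kind == "lowpass":
        params["tau"] = overrides.pop("tau", 1.0)
    elif kind == "kernel_integral":
        params["kernel"] = overrides.pop("kernel", KernelSpec.from_mixture(0.5))
    params.update(overrides)
    return RegulatorSpec(kind, k=k, **params)
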