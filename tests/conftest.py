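import numpy as np
import pytest

from holocorr import (
    Coupling,
    LayerSpec,
    ModuleSpec,
    NetworkParams,
    OmicsLayer,
    SimulationSpec,
    simulate_bundle,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture
def small_layer(rng):
    """10 samples x 6 features of plain Gaussian noise."""
    return OmicsLayer(
        layer_id="toy",
        sample_ids=[f"s{i}" for i in range(10)],
        feature_ids=[f"f{j}" for j in range(6)],
        values=rng.standard_normal((10, 6)),
    )


def make_layer(values, layer_id="L", prefix_s="s", prefix_f="f"):
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    return OmicsLayer(
        layer_id,
        [f"{prefix_s}{i + 1}" for i in range(n)],
        [f"{prefix_f}{j + 1}" for j in range(p)],
        values,
    )


@pytest.fixture
def planted_layer_spec():
    """Four 40-feature modules at loading 0.85 plus 40 background features."""
    return SimulationSpec(
        n_samples=40,
        layers=[
            LayerSpec(
                "host",
                [ModuleSpec(f"A{i}", 40, 0.85) for i in range(1, 5)],
                n_background_features=40,
            )
        ],
        seed=0,
    )


@pytest.fixture
def coupled_spec():
    """Two layers, one planted coupling at rho = 0.8."""
    return SimulationSpec(
        n_samples=40,
        layers=[
            LayerSpec("host", [ModuleSpec(f"A{i}", 40, 0.85) for i in (1, 2)], 20),
            LayerSpec("micro", [ModuleSpec(f"B{i}", 40, 0.85) for i in (1, 2)], 20),
        ],
        couplings=[Coupling("host", "A1", "micro", "B1", 0.8)],
        seed=0,
    )


@pytest.fixture
def fitted_params():
    """Detection settings used for planted-module analyses (fixed power)."""
    return NetworkParams(power=6)


@pytest.fixture
def demo_bundle(coupled_spec):
    return simulate_bundle(coupled_spec, seed=11)
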