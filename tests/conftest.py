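import numpy as np
import pytest

from lamina_quant.phantom import PhantomSpec, analytic_morphometry, draw_spec, generate_phantom


@pytest.fixture(scope="session")
def default_spec() -> PhantomSpec:
    return PhantomSpec.create(seed=7)


@pytest.fixture(scope="session")
def default_scene(default_spec):
    return generate_phantom(default_spec)


@pytest.fixture(scope="session")
def default_truth(default_spec):
    return analytic_morphometry(default_spec)


@pytest.fixture(scope="session")
def small_cohort():
    """Six mixed-preset scenes with analytic truth, shared across tests."""
    rng = np.random.default_rng(11)
    out = []
    for i in range(6):
        spec = draw_spec(rng, preset="normal" if i % 2 == 0 else "glaucoma")
        out.append((spec, generate_phantom(spec), analytic_morphometry(spec)))
    return out
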