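import numpy as np
import pandas as pd
import pytest

from clpnet import SymptomPanel, GeneratorSpec, generate_panel, make_scenarios


@pytest.fixture(scope="session")
def chronic_panel():
    """One chronic-scenario draw (n=1000) with its ground truth."""
    spec = make_scenarios(n=1000, seed=11)["chronic"]
    return generate_panel(spec)


@pytest.fixture(scope="session")
def small_cohort():
    """Mixed 4-scenario cohort, 200 subjects per scenario."""
    from clpnet.simulate import generate_cohort

    return generate_cohort(n_per_group=200, seed=5)


@pytest.fixture()
def tiny_panel():
    """Hand-written 4-subject panel for exact arithmetic checks."""
    t1 = np.array(
        [
            [0, 0, 0, 0, 0, 0, 0, 0, 0],
            [1, 0, 2, 1, 0, 1, 0, 1, 1],
            [3, 3, 3, 3, 3, 3, 3, 3, 3],
            [1, 1, 1, 0, 0, 0, 1, 1, 1],
        ]
    )
    t2 = np.array(
        [
            [0, 1, 0, 0, 0, 0, 0, 0, 0],
            [2, 1, 2, 1, 1, 1, 0, 1, 1],
            [1, 1, 0, 1, 0, 1, 0, 1, 0],
            [0, 0, 0, 0, 0, 0, 0, 0, 1],
        ]
    )
    return SymptomPanel(subject_id=np.array(["a", "b", "c", "d"]), scores_t1=t1, scores_t2=t2)


@pytest.fixture()
def identity_panel():
    """Panel where wave 2 reproduces wave 1 exactly (deterministic diagonal)."""
    rng = np.random.default_rng(42)
    t1 = rng.integers(0, 4, size=(300, 9))
    return SymptomPanel(subject_id=np.arange(300), scores_t1=t1, scores_t2=t1.copy())


@pytest.fixture()
def noise_spec():
    """Generator spec with no cross-lag structure at all."""
    return GeneratorSpec(n=100, true_B=np.zeros((9, 9)), latent_cov_t1=np.eye(9), seed=3)
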