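import numpy as np
import pytest

from orchardseg.synthetic import SceneSpec, generate_scene


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture(scope="session")
def swcr_scene():
    """A well-lit low-weed scene with ground truth."""
    return generate_scene(SceneSpec.for_stratum("SB", "SWCR", seed=101))


@pytest.fixture(scope="session")
def lwcr_scene():
    """A well-lit heavily weeded scene with ground truth."""
    return generate_scene(SceneSpec.for_stratum("SB", "LWCR", seed=101))


@pytest.fixture(scope="session")
def ib_scene():
    """An under-lit scene with ground truth."""
    return generate_scene(SceneSpec.for_stratum("IB", "SWCR", seed=101))


@pytest.fixture(scope="session")
def small_scene_specs():
    """Compact scene specs used where many scenes are rendered."""
    return [
        SceneSpec.for_stratum(bc, wcc, seed=seed, height=100, width=100, n_trees=9)
        for seed, (bc, wcc) in enumerate(
            [("SB", "SWCR"), ("IB", "MWCR"), ("SB", "LWCR"), ("IB", "SWCR")]
        )
    ]
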