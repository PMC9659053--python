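import numpy as np
import pytest

from oolemma.synthetic import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Balanced 4+4 cohort at reduced raster size, moderate class effect.

    Session-scoped: rendering is the slow part and the cohort is
    immutable, so evaluation tests share one instance.
    """
    cfg = CohortConfig(n_ruptured=4, n_nonruptured=4, frame_width=160,
                       frame_height=120, frames_per_movie=31,
                       class_effect=2.0, master_seed=123)
    return generate_cohort(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
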