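import pytest

from scenegram import (exp1_config, exp2_config, generate_exp1,
                       generate_exp2)


@pytest.fixture(scope="session")
def exp1_ds():
    """Default Experiment-1-style dataset (build + recall), fixed seed."""
    return generate_exp1(exp1_config(seed=11))


@pytest.fixture(scope="session")
def exp2_ds():
    """Default Experiment-2-style dataset (build + search), fixed seed."""
    return generate_exp2(exp2_config(seed=11))


@pytest.fixture(scope="session")
def small_ds():
    """Small dataset (4 participants, 8 rooms) for cheap structural tests."""
    return generate_exp1(exp1_config(seed=7, n_participants=4,
                                     rooms_per_category=2))
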