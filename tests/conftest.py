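import numpy as np
import pytest

import mchequity as me


@pytest.fixture(scope="session")
def small_survey():
    """A 400-household survey with one pro-rich and one pro-poor indicator."""
    cfg = me.default_config(
        n_households=400,
        indicators=[
            me.IndicatorSpec("coverage_x", "coverage", alpha=-1.0, beta=0.8,
                             residence_effect=0.4, education_effect=0.5),
            me.IndicatorSpec("outcome_y", "outcome", alpha=-1.5, beta=-0.8,
                             residence_effect=-0.3),
        ],
        seed=42,
    )
    return me.generate_survey(cfg)


@pytest.fixture(scope="session")
def null_survey():
    """A survey whose indicators carry no wealth effect (beta = 0)."""
    cfg = me.default_config(
        n_households=5000,
        indicators=[me.IndicatorSpec("flat", alpha=-1.4, beta=0.0)],
        seed=11,
    )
    return me.generate_survey(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
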