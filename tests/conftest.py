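import numpy as np
import pytest

import dcemix as dx
from dcemix.estimation import MixedLogitSpec

PRESET_MIXING = {
    "side_effect_severity": "normal",
    "future_side_effect_risk": "normal",
    "symptom_reduction": "normal",
    "death_risk_reduction": "normal",
    "cost": "triangular",
}


@pytest.fixture(scope="session")
def preset():
    """Study-scale population and design (161 respondents, 4 x 10 tasks)."""
    return dx.study_emulation_preset()


@pytest.fixture(scope="session")
def preset_data(preset):
    pop, design = preset
    return dx.simulate_dataset(pop, design, seed=7)


@pytest.fixture(scope="session")
def clogit_spec(preset):
    _, design = preset
    return MixedLogitSpec(attributes=tuple(design.factor_names), n_draws=1)


@pytest.fixture(scope="session")
def clogit_result(clogit_spec, preset_data):
    return dx.fit(clogit_spec, preset_data)


@pytest.fixture(scope="session")
def mixed_spec(preset):
    _, design = preset
    return MixedLogitSpec(
        attributes=tuple(design.factor_names),
        mixing=dict(PRESET_MIXING),
        interactions=(("cost", "phi"),),
        n_draws=200,
    )


@pytest.fixture(scope="session")
def mixed_result(mixed_spec, preset_data):
    return dx.fit(mixed_spec, preset_data)


@pytest.fixture
def small_factors():
    return [
        dx.FactorSpec("price", (0.0, 10.0, 20.0), -1),
        dx.FactorSpec("efficacy", (0.0, 50.0), +1),
        dx.FactorSpec("doses", (1.0, 2.0, 3.0), -1),
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)
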