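import numpy as np
import pytest
from hypothesis import HealthCheck, settings as hyp_settings

from psybayes import (
    SamplerSettings,
    fit_color,
    fit_linear,
    fit_reaction_time,
    fit_success_rate,
    fit_ttest,
    generate_adaptation,
    generate_afterimages,
    generate_flanker,
)

hyp_settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
hyp_settings.load_profile("default")

# small but honest sampler settings: fixtures are shared across the suite so
# the heavier hierarchical fits run once
FAST = SamplerSettings(chains=2, warmup=600, iter=600, seed=42)


@pytest.fixture(scope="session")
def flanker():
    """Synthetic flanker datasets (reaction times + correctness) at reduced size."""
    return generate_flanker(n_per_group=8, trials=40, seed=5)


@pytest.fixture(scope="session")
def rt_fit(flanker):
    rt, _ = flanker
    sub = rt.frame[(rt.frame.group == "control") & (rt.frame.correct == 1)]
    return fit_reaction_time(sub[["subject", "rt", "correct"]], settings=FAST)


@pytest.fixture(scope="session")
def ttest_data():
    return np.random.default_rng(1).normal(5.0, 2.0, 2000)


@pytest.fixture(scope="session")
def ttest_fit(ttest_data):
    return fit_ttest(ttest_data, settings=SamplerSettings(4, 500, 500, seed=7))


@pytest.fixture(scope="session")
def success_fit(flanker):
    _, cr = flanker
    sub = cr.frame[cr.frame.group == "control"]
    return fit_success_rate(sub[["subject", "result"]], settings=FAST)


@pytest.fixture(scope="session")
def adaptation():
    return generate_adaptation(seed=4)


@pytest.fixture(scope="session")
def linear_fits(adaptation):
    fits = []
    for g in (1, 2):
        sub = adaptation.frame[adaptation.frame.group == g]
        fits.append(fit_linear(sub[["subject", "sequence", "response"]], settings=FAST))
    return fits


@pytest.fixture(scope="session")
def afterimages():
    return generate_afterimages(seed=6)


@pytest.fixture(scope="session")
def color_fit(afterimages):
    red = afterimages.frame[afterimages.frame.stimulus == "red"]
    return fit_color(red[["r", "g", "b"]], settings=SamplerSettings(2, 400, 400, seed=9))
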