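import pytest

from chromasupp.hrf import (
    CONDITIONS,
    BlockTimeCourse,
    ConditionParams,
    HRFTemporalParams,
    TimeGrid,
    model_response,
)

#: Reduced-resolution display used where a rendering property does not
#: depend on pixel density; keeps the image tests fast.
from chromasupp.stimuli import DisplayGeometry

SMALL_DISPLAY = DisplayGeometry(69.0, (31.5, 25.2), (320, 256))


@pytest.fixture(scope="session")
def true_temporal():
    return HRFTemporalParams(T1=6.0, T2=16.0, alpha1=2.5, alpha2=4.0)


@pytest.fixture(scope="session")
def true_condition_params(true_temporal):
    """Four condition parameter sets with distinct amplitudes."""
    grid = TimeGrid()
    out = {}
    for c, peak in zip(CONDITIONS, (3.23, 3.06, 3.11, 3.16)):
        cp = ConditionParams(a1=1.0, a2=-0.35, b=0.004, d=0.2, condition=c)
        scale = peak / model_response(true_temporal, cp, grid).max()
        out[c] = ConditionParams(a1=scale, a2=-0.35 * scale, b=0.004, d=0.2,
                                 condition=c)
    return out


@pytest.fixture(scope="session")
def noise_free_data(true_temporal, true_condition_params):
    grid = TimeGrid()
    return [
        BlockTimeCourse(c, model_response(true_temporal,
                                          true_condition_params[c], grid))
        for c in CONDITIONS
    ]


@pytest.fixture(scope="session")
def small_display():
    return SMALL_DISPLAY
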