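import numpy as np
import pytest

from seasonomics.cohort import CohortDesign, FeatureSpec, generate_features, generate_visits


@pytest.fixture(scope="session")
def desk_design():
    return CohortDesign(n_subjects=40, n_years=3, visits_per_year=4, seed=11)


@pytest.fixture(scope="session")
def desk_visits(desk_design):
    return generate_visits(desk_design)


@pytest.fixture(scope="session")
def seasonal_long(desk_design, desk_visits):
    """One pattern-1 seasonal feature at SNR 3 plus one null feature."""
    specs = [
        FeatureSpec("season1", kind="seasonal_p1", amplitude=3.0, phase_jitter=0.0),
        FeatureSpec("flat", kind="null", amplitude=0.0),
    ]
    long, truth = generate_features(desk_design, specs, desk_visits)
    return long, truth
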