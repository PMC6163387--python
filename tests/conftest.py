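from datetime import date

import pytest

import mothtraj as mt

#: equatorial release shared by the analytic-oracle tests
RELEASE = (0.0, 0.0)
NIGHT = date(2000, 3, 1)


@pytest.fixture(scope="session")
def uniform_field():
    """Uniform southerly 10 m/s field on an equatorial oracle domain."""
    field, _ = mt.load_preset("uniform_test")
    return field


@pytest.fixture(scope="session")
def study():
    field, cfg = mt.load_preset("study_nights")
    return field, cfg


@pytest.fixture(scope="session")
def study_runs(study):
    """Passive and behavioral ensembles on the three-night preset (dt=60 s)."""
    field, cfg = study
    return mt.run_from_config(cfg, field)
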