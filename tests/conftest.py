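import numpy as np
import pytest

import suzukii_morphs as sm

# fixed a priori for all stochastic tests
STUDY_SEED = 20200206


@pytest.fixture(scope="session")
def specs():
    return sm.default_lab_specs()


@pytest.fixture(scope="session")
def lab(specs):
    """One synthetic laboratory study at the default (published) parameters."""
    return sm.generate_lab_dataset(specs, STUDY_SEED)


@pytest.fixture(scope="session")
def fits(lab):
    return {sex: sm.fit_summer_allometry(lab, sex) for sex in sm.Sex}


@pytest.fixture(scope="session")
def field(specs):
    season = sm.default_season_spec(specs)
    return sm.generate_field_season(season, STUDY_SEED + 1)


@pytest.fixture()
def rng():
    return np.random.default_rng(STUDY_SEED)


def toy_records(values, labels, sex=sm.Sex.FEMALE, prefix="toy"):
    """Lab records with wing_length carrying the toy values."""
    return sm.MorphometricDataset(
        [
            sm.FlyRecord(
                id=f"{prefix}-{i}",
                sex=sex,
                source=sm.Source.LAB,
                morph=m,
                wing_length=v,
                hind_tibia=1.0,
            )
            for i, (v, m) in enumerate(zip(values, labels))
        ]
    )
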