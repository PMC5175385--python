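import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import erdentropy as ee

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def toy16():
    return ee.build_montage("toy16")


@pytest.fixture(scope="session")
def full63():
    return ee.build_montage("full63")


@pytest.fixture(scope="session")
def small_study():
    """A tiny but complete two-group, two-task study used across tests."""
    cfg = ee.SimConfig(
        n_per_group=4,
        tasks=("finger_sequence", "pinch_grip"),
        trials_per_task=8,
        n_baseline_segments=6,
        seed=123,
    )
    return ee.simulate_study(cfg)


@pytest.fixture(scope="session")
def small_tables(small_study):
    from erdentropy.pipeline import build_metric_tables, participant_spectra

    spectra = participant_spectra(small_study)
    tables, bin_table = build_metric_tables(
        small_study, spectra, ((8.0, 25.0), (13.0, 19.0))
    )
    return spectra, tables, bin_table


def make_epochs(data, fs, montage, state="movement"):
    return ee.EpochSet(data=np.asarray(data, float), fs=fs, montage=montage, state=state)
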