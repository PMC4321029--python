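import pytest

from f1screen import ScreenConfig, datasets, score_screen


@pytest.fixture(scope="session")
def screen_df():
    return datasets.load_screen_table()


@pytest.fixture(scope="session")
def screen_tallies():
    return datasets.load_screen_tallies()


@pytest.fixture(scope="session")
def screen_records(screen_tallies):
    return score_screen(screen_tallies, ScreenConfig())


@pytest.fixture(scope="session")
def submap_cases():
    return {c.case_id: c for c in datasets.load_submap_cases()}


@pytest.fixture(scope="session")
def annotation():
    return datasets.load_annotation()
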