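import pytest

from narramine import synthetic


@pytest.fixture(scope="session")
def small_bundle():
    """A small symmetric synthetic corpus with exact truth (seed-fixed)."""
    config = synthetic.symmetric_preset(n_participants=3, narrative_rate=4.0)
    return synthetic.generate(config, seed=7)


@pytest.fixture(scope="session")
def study_bundle():
    """One realization of the study-shape preset (34 vs 24 participants)."""
    return synthetic.generate(synthetic.study_preset(), seed=1)


@pytest.fixture(scope="session")
def toy_lexicon_path():
    from importlib.resources import files

    return str(files("narramine").joinpath("data/toy_lexicon.tsv"))


@pytest.fixture(scope="session")
def toy_stoplist_path():
    from importlib.resources import files

    return str(files("narramine").joinpath("data/toy_stoplist.txt"))
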