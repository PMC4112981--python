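import pytest

from steroidxr import KeyDictionary, load_compound_library, load_fixture_panel


@pytest.fixture(scope="session")
def library():
    """Packaged compound library, standardized."""
    return load_compound_library()


@pytest.fixture(scope="session")
def dictionary():
    return KeyDictionary.load()


@pytest.fixture(scope="session")
def panels():
    """All five packaged fixture panels keyed by assay name."""
    return {
        name: load_fixture_panel(name)
        for name in ("cortisol", "dhea_sulfate", "estradiol", "progesterone", "testosterone")
    }
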