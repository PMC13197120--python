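import pytest

from idap.fixtures import FixtureSpec, make_toy_cohort
from idap.lexicon import build_lexicon


@pytest.fixture(scope="session")
def seed7_bundle(tmp_path_factory):
    """The seed-7 synthetic evidence bundle, generated once per session."""
    out = tmp_path_factory.mktemp("bundle7")
    manifest = make_toy_cohort(FixtureSpec(seed=7), out)
    return out, manifest


@pytest.fixture
def toy_lexicon():
    return build_lexicon(
        [
            ("Fostamatinib", []),
            ("Imatinib", ["Gleevec"]),
            ("Imatinib Mesylate", []),
            ("Erlotinib", []),
        ]
    )
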