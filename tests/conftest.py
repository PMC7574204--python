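import pytest

from scofuel import reference as ref
from scofuel.fame import profile_from_items
from scofuel.synthetic import write_fixture_tree


@pytest.fixture
def as_psh_profile():
    """AS-PSH-grown oil FAME composition as printed (sums to 96.70 %)."""
    return profile_from_items("as-psh", ref.AS_PSH_FAME.items())


@pytest.fixture
def ad_psh_profile():
    return profile_from_items("ad-psh", ref.AD_PSH_FAME.items())


@pytest.fixture
def ynb_profile():
    return profile_from_items("ynb", ref.YNB_FAME.items())


@pytest.fixture(scope="session")
def fixture_tree(tmp_path_factory):
    """A complete demo dataset tree generated once per session."""
    outdir = tmp_path_factory.mktemp("fixtures")
    return write_fixture_tree(outdir, seed=11)
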