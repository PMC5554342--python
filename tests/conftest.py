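import pytest

from conceptboard import control
from conceptboard.blackboard import make_blackboard
from conceptboard.fixtures import fixture


def build_and_parse(name: str, record: bool = False):
    fx = fixture(name)
    bb = make_blackboard(fx.vocabulary, fx.pool_sizes)
    script, trace, onsets = control.parse(fx.tokens, fx.lexicon, bb, record=record)
    return fx, bb, trace, onsets


@pytest.fixture(scope="session")
def parsed_cat_is_on_mat():
    """*cat is on mat* parsed into a fresh blackboard (shared, read-only)."""
    return build_and_parse("cat-is-on-mat")


@pytest.fixture(scope="session")
def parsed_cat_sees_cat():
    return build_and_parse("cat-sees-cat")


@pytest.fixture(scope="session")
def parsed_bill_gates():
    """The nine-word sentence with its recorded activity trace."""
    return build_and_parse("bill-gates", record=True)
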