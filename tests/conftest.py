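import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def tiny_table():
    """The two-column, two-row table from the dialect examples."""
    from garm import parse_table

    return parse_table("x,y\na,b\na,\n")


@pytest.fixture
def grocery_table():
    """A small shopping-survey style table used for rendering tests."""
    from garm import parse_table

    rows = [
        "age,bread,onions,butter",
        "A,y,n,y",
        "B,y,y,y",
        "A,n,n,y",
        "C,n,y,n",
        "B,y,n,y",
        "C,y,y,n",
    ]
    return parse_table("\n".join(rows) + "\n")
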