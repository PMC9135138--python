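"""Exception hierarchy.

Everything user-facing derives from :class:`GarmError` so the CLI can catch
one type and exit nonzero with a clean diagnostic.
"""


class GarmError(Exception):
    """Base class for all errors raised by garm."""


class FormatError(GarmError):
    """The input table violates the CSV dialect (ragged row, bad character, ...)."""


class PatternError(GarmError):
    """A rule pattern or rule expression does not parse under the grammar."""


class ConfigError(GarmError):
    """A search configuration is inconsistent or unusable for the given table."""


class ContractError(GarmError):
    """An internal precondition was violated (programming error, not user input)."""


class FixtureError(GarmError):
    """A synthetic fixture specification cannot be realized with exact counts."""
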