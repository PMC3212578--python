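"""Exception hierarchy for arscore.

All errors raised on bad input derive from :class:`ArscoreError` so callers
(and the CLI) can distinguish usage problems from genuine bugs.
"""


class ArscoreError(Exception):
    """Base class for all arscore errors."""


class ParseError(ArscoreError):
    """A file could not be parsed; the message names the offending location."""


class FormatError(ArscoreError):
    """A file parsed but violates the format's structural contract."""


class ContractError(ArscoreError):
    """An operation's precondition is violated (bad shapes, empty groups, ...)."""


class NotEvaluableError(ArscoreError):
    """A pathway pair cannot be scored (e.g. residual set too small).

    Distinct from a correlation of zero: the quantity is undefined, not null.
    """
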