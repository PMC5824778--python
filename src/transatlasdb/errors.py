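"""Exception hierarchy.

``TadError`` covers everything the toolkit raises on purpose; ``TadUserError``
marks conditions caused by user input (bad files, bad queries, bad flags) that
the command line maps to exit status 1, as opposed to internal faults (2).
"""


class TadError(Exception):
    """Base class for all toolkit errors."""


class TadUserError(TadError):
    """Error attributable to user input or state (exit status 1)."""


class StoreExistsError(TadUserError):
    """A store is already installed at the target path."""


class ValidationError(TadUserError):
    """Input data violates a documented requirement; message names the field."""


class DialectError(TadUserError):
    """A results file does not match any accepted program dialect."""


class QuerySyntaxError(TadUserError):
    """SQL-subset parse failure; carries the character position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


class UnsupportedConstructError(TadUserError):
    """Query uses a construct outside the supported SQL subset (OR, JOIN...)."""
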