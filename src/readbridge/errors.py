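"""Typed errors raised across the toolkit.

Every reader and pipeline stage either returns a parsed result (possibly
with a report of recoverable problems) or raises one of these; nothing
escapes as a bare exception from user input.
"""


class ReadbridgeError(Exception):
    """Base class for all toolkit errors."""


class MalformedCodeError(ReadbridgeError, ValueError):
    """A code string violates the conventions of its code system."""


class VersionConflictError(ReadbridgeError, ValueError):
    """An embedded Read-version prefix disagrees with the declared version."""


class SchemaError(ReadbridgeError, ValueError):
    """A tabular input is missing a required column."""


class DuplicateKeyError(ReadbridgeError, ValueError):
    """A key column that must be unique contains repeated values."""


class ParseError(ReadbridgeError, ValueError):
    """A cell could not be parsed; carries the offending row number."""


class UnknownCodeError(ReadbridgeError, KeyError):
    """A code was looked up in a dictionary that does not contain it."""


class FlagLookupError(ReadbridgeError, KeyError):
    """A mapping record's target has no corresponding flagged entry."""


class ReplacementCycleError(ReadbridgeError, ValueError):
    """A chain of concept replacements loops back on itself."""

    def __init__(self, chain):
        self.chain = list(chain)
        super().__init__("replacement chain cycle: " + " -> ".join(self.chain))
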