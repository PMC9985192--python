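"""Exception hierarchy for phenocheck.

All library errors derive from :class:`PhenocheckError` so callers (and the
CLI) can distinguish curation-tool failures from programming errors.
"""

from __future__ import annotations


class PhenocheckError(Exception):
    """Base class for all phenocheck errors."""


class ParseError(PhenocheckError):
    """A file could not be parsed as the expected tab-delimited contract.

    Carries a human-readable message naming the offending line/cell where
    possible.
    """


class MalformedValueEntryError(ParseError):
    """A value=meaning cell lacked an ``=`` or had an empty code side."""

    def __init__(self, text: str, context: str = ""):
        self.text = text
        msg = f"malformed value=meaning entry: {text!r}"
        if context:
            msg += f" ({context})"
        super().__init__(msg)


class AlignmentError(PhenocheckError):
    """Data set and data dictionary could not be aligned by variable name."""

    def __init__(self, message: str, only_in_dataset=(), only_in_dictionary=()):
        self.only_in_dataset = list(only_in_dataset)
        self.only_in_dictionary = list(only_in_dictionary)
        super().__init__(message)


class FixtureSpecError(PhenocheckError):
    """A synthetic-fixture specification is internally inconsistent."""


class InjectionError(PhenocheckError):
    """An error kind is not applicable to the given fixture."""


class ConfigError(PhenocheckError):
    """A configuration file or option could not be interpreted."""
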