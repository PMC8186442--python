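"""Exception hierarchy for rsvstab.

All package errors derive from :class:`RsvStabError` so callers can catch one
base class; subclasses mirror the distinct failure contracts (format vs value
validation vs cross-object consistency vs insufficient data).
"""


class RsvStabError(Exception):
    """Base class for all rsvstab errors."""


class FormatError(RsvStabError):
    """Input file is structurally malformed (bad header, empty file, ...)."""


class ValidationError(RsvStabError):
    """A value violates a domain invariant (RSV outside [0, 100], ...)."""


class ConsistencyError(RsvStabError):
    """Two objects that must describe the same data do not match."""


class InsufficientDataError(RsvStabError):
    """Too few present values / units / days for the requested statistic."""


class FixtureNotFoundError(RsvStabError, LookupError):
    """Unknown bundled fixture name."""


class StateError(RsvStabError):
    """Operation called in the wrong protocol phase."""


class ConfigError(RsvStabError):
    """Invalid synthetic-generator configuration."""
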