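"""Exception hierarchy shared across the pipeline.

All user-facing failures derive from :class:`TriadscopeError` so the CLI can
map them onto exit code 1 (validation) versus 2 (usage).
"""


class TriadscopeError(Exception):
    """Base class for all triadscope errors."""


class FormatError(TriadscopeError):
    """A file does not have the expected structure (missing columns, bad TSV)."""


class ValidationError(TriadscopeError):
    """Well-formed input whose content violates a domain invariant."""


class AmbiguityError(ValidationError):
    """Input admits more than one interpretation where exactly one is required."""


class ConfigurationError(TriadscopeError):
    """Invalid parameter combination or run configuration."""


class EmptyInputError(ValidationError):
    """An operation requiring data received none."""
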