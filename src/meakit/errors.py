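"""Exception hierarchy shared across the package.

All data-facing errors derive from :class:`MeakitError` so callers (and the
CLI) can distinguish usage problems from malformed input.
"""


class MeakitError(Exception):
    """Base class for all meakit-raised errors."""


class FormatError(MeakitError):
    """A file does not conform to the documented on-disk schema."""


class ValidationError(MeakitError):
    """An in-memory object violates one of its invariants."""


class ParameterError(MeakitError):
    """A configuration value is outside its valid range."""


class ElectrodeLookupError(MeakitError, KeyError):
    """An electrode label or coordinate does not exist in a layout/table."""

    def __str__(self) -> str:  # KeyError quotes its message; keep it readable
        return Exception.__str__(self)
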