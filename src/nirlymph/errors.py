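"""Exception hierarchy.

All user-input problems derive from :class:`InvalidInputError` (a ValueError)
so callers can catch one type; geometry and file-format problems get their
own subclasses because the CLI maps them to distinct exit codes.
"""


class NirlymphError(Exception):
    """Base class for all package errors."""


class InvalidInputError(NirlymphError, ValueError):
    """A value, trace or parameter violates a documented precondition."""


class InvalidGeometryError(InvalidInputError):
    """An ROI or measurement line does not fit the image."""


class UndefinedMeanError(NirlymphError):
    """Fewer than two peaks: no inter-peak interval, so no instantaneous mean."""


class ProcessingError(NirlymphError, RuntimeError):
    """Too many per-frame failures while tracking a stack."""


class FormatError(NirlymphError, ValueError):
    """A file could not be parsed in the expected format."""
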