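"""Exception hierarchy used across the package."""


class KindleIctalError(Exception):
    """Base class for package errors."""


class InvalidArgumentError(KindleIctalError, ValueError):
    """An argument violates a documented precondition."""


class ParseError(KindleIctalError, ValueError):
    """A file could not be parsed; the message names the offending field."""


class ConflictError(KindleIctalError, ValueError):
    """A planted event overlaps an existing one."""


class AliasingError(InvalidArgumentError):
    """A requested frequency is at or above the Nyquist frequency."""


class UnitError(KindleIctalError, ValueError):
    """Trace units are incompatible with an absolute-threshold rule."""


class DataError(KindleIctalError, ValueError):
    """The input samples are unusable (e.g. NaN)."""


class AlignmentError(KindleIctalError, ValueError):
    """Two traces do not share a sampling rate / time base."""
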