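"""Exception hierarchy.

All errors raised by the package derive from :class:`SegfuseError`, split into
validation failures (bad labels, inconsistent grids, bad parameters) and I/O
failures, so callers — in particular the CLI — can map them to distinct exit
codes.
"""


class SegfuseError(Exception):
    """Base class for all package errors."""


class ValidationError(SegfuseError, ValueError):
    """Input violates a contract (labels, parameters, consistency)."""


class ShapeMismatchError(ValidationError):
    """Voxel grids that must agree do not."""


class LabelError(ValidationError):
    """A label value outside the permitted set was encountered."""


class IOValidationError(SegfuseError, OSError):
    """A file could not be read or written."""
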