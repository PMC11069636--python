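"""Exception hierarchy shared across the package.

The CLI maps these onto exit codes: usage/config errors -> 2,
data/format errors -> 3, capability (missing optional backend) -> 4.
"""


class ThumbrotError(Exception):
    """Base class for all package errors."""


class DomainError(ThumbrotError, ValueError):
    """A value violates a kinematic or geometric domain constraint."""


class DegenerateGeometryError(DomainError):
    """A geometric computation is undefined (coincident points, zero-length
    reference segment, ...)."""


class ProjectionError(DomainError):
    """A 3D point cannot be projected (behind the camera)."""


class FormatError(ThumbrotError, ValueError):
    """A landmark/feature file does not match its declared dialect."""


class UsageError(ThumbrotError, ValueError):
    """The caller combined arguments in an unsupported way."""


class CapabilityError(ThumbrotError, RuntimeError):
    """An optional capability (e.g. a live pose-estimation backend) is not
    installed or not registered."""


class FitError(ThumbrotError, RuntimeError):
    """Model fitting failed (singular design, degenerate labels, ...)."""
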