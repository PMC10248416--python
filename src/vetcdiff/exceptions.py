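"""Exception hierarchy shared across the package."""


class VetcdiffError(Exception):
    """Base class for all package errors."""


class DomainError(VetcdiffError, ValueError):
    """An argument lies outside a function's mathematical domain."""


class TimingError(VetcdiffError, ValueError):
    """Gradient timing parameters are inconsistent (e.g. big_delta <= small_delta/3)."""


class ConfigError(VetcdiffError, ValueError):
    """A configuration object violates its invariants."""


class InsufficientDataError(VetcdiffError, ValueError):
    """Fewer data points than free parameters + 1."""


class DegenerateDataError(VetcdiffError, ValueError):
    """Input data carry no usable signal (e.g. all-equal values, zero margin)."""


class AlignmentError(VetcdiffError, ValueError):
    """Arrays that must share a voxel grid do not."""


class GeometryError(VetcdiffError, ValueError):
    """A lesion or mask does not fit the requested grid."""


class DkiValidityWarning(UserWarning):
    """A DKI evaluation was requested beyond the kurtosis validity bound b*D*K <= 3."""
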