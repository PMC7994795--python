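"""Exception hierarchy.

Every error raised on purpose by this package derives from
:class:`VolstormError`, so callers can catch pipeline failures without
masking programming errors.
"""


class VolstormError(Exception):
    """Base class for all volstorm errors."""


class FormatError(VolstormError):
    """A localization file does not conform to its declared dialect."""


class ParameterError(VolstormError, ValueError):
    """An operation was called with an invalid parameter value."""


class DataError(VolstormError):
    """Input data are structurally valid but insufficient for the operation."""


class CalibrationError(VolstormError):
    """The astigmatic calibration cannot be established (e.g. no resolvable
    astigmatism, non-monotone discriminant)."""


class FiducialError(VolstormError):
    """Fiducial beads are missing, too few, or unmatched."""


class SpecMismatchError(VolstormError):
    """Provided data do not match the declared scan specification."""
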