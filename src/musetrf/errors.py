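"""Exception and warning types shared across the pipeline."""


class MusetrfError(Exception):
    """Base class for all package errors."""


class FormatError(MusetrfError):
    """A file could not be parsed as the expected format."""


class MonophonyError(MusetrfError):
    """A melody violates the monophony contract (overlapping/simultaneous notes)."""


class DegenerateMelodyError(MusetrfError):
    """A melody is too short for the requested derivation."""


class EmptyModelError(MusetrfError):
    """A sequence model has neither training data nor a declared alphabet."""


class AlphabetError(MusetrfError):
    """Two distributions are defined over different alphabets."""


class ConfigError(MusetrfError):
    """Invalid configuration value."""


class AlignmentError(MusetrfError):
    """Arrays that must be aligned (notes vs estimates, tables vs tables) are not."""


class DataError(MusetrfError):
    """Input data are unusable (non-finite, missing)."""


class DataQualityError(MusetrfError):
    """Data quality control failed irrecoverably (e.g., every channel flagged)."""


class InterpolationError(MusetrfError):
    """A bad channel has no neighbors to interpolate from."""


class PowerWarning(UserWarning):
    """Sample size is too small for the statistical procedure to be well powered."""


class DataQualityWarning(UserWarning):
    """Data quality is suspect (e.g., excessive trial rejection) but analysis continues."""
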