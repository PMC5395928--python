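"""Exception hierarchy for the pipeline.

Every stage raises a subclass of :class:`NirsconnError` so callers can
distinguish pipeline failures from programming errors.
"""


class NirsconnError(Exception):
    """Base class for all package errors."""


class MontageError(NirsconnError):
    """Invalid probe geometry (non-involutive mirror map, bad ROI partition...)."""


class FormatError(NirsconnError):
    """Malformed on-disk file or unknown wavelength/channel labelling."""


class SamplingError(NirsconnError):
    """Non-uniform or inconsistent time base in a recording."""


class LengthError(NirsconnError):
    """Series too short for the requested operation (filtering, trimming)."""


class ModelError(NirsconnError):
    """Ill-conditioned optical model (singular extinction matrix)."""


class QCError(NirsconnError):
    """Quality control failure that must halt the analysis."""


class ConfigurationError(NirsconnError):
    """Invalid simulation or pipeline configuration."""


class NoSeedError(NirsconnError):
    """Localizer found no significantly activated channel; rsFC cannot proceed."""


class EstimationError(NirsconnError):
    """Rank-deficient or collinear design in a regression."""
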