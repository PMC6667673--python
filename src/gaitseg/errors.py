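"""Exception hierarchy shared by all gaitseg modules."""


class GaitsegError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(GaitsegError, ValueError):
    """A parameter is outside its admissible range (e.g. cutoff >= Nyquist)."""


class InsufficientDataError(GaitsegError, ValueError):
    """A signal is too short for the requested operation."""


class AlignmentError(GaitsegError, ValueError):
    """Time series that must share rate/origin/length do not."""


class DegenerateGeometryError(GaitsegError, ValueError):
    """Coincident marker points or zero-length segment vectors."""


class DegenerateGaitError(GaitsegError, ValueError):
    """Gait-model parameters imply no usable movement (zero range of motion)."""


class ConfigurationError(GaitsegError, ValueError):
    """A detector rule was enabled without the inputs it needs."""


class LoadError(GaitsegError, ValueError):
    """A trial bundle or CSV stream could not be loaded consistently."""
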