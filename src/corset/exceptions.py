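"""Exception hierarchy shared across the package."""


class CorsetError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(CorsetError, ValueError):
    """A generator or model parameter is outside its admissible range."""


class DataError(CorsetError, ValueError):
    """Input data violate a contract (e.g. non-positive reference signal)."""


class FitError(CorsetError, RuntimeError):
    """A curve fit failed or the data carry no signal to fit."""


class TopologyError(CorsetError, ValueError):
    """A mesh cannot be built with the requested discretization."""


class CalibrationError(CorsetError, RuntimeError):
    """Root-finding for the contractility calibration has no bracket."""
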