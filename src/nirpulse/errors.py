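"""Exception hierarchy for nirpulse."""


class NirPulseError(Exception):
    """Base class for all nirpulse errors."""


class ConfigurationError(NirPulseError):
    """Invalid configuration: bad band count, singular system matrix, bad ROI."""


class InputError(NirPulseError):
    """Invalid data input: negative sigma, too-short series, band outside Nyquist."""


class NumericalError(NirPulseError):
    """Numerically unusable operation, e.g. an ill-conditioned matrix solve."""


class EstimationError(NirPulseError):
    """An estimate is undefined for the given data, e.g. heart rate from <2 peaks."""
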