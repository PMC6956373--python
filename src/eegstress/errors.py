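"""Exception hierarchy shared across the pipeline."""


class EegStressError(Exception):
    """Base class for package-specific errors."""


class DimensionError(EegStressError, ValueError):
    """An array does not have the expected shape."""


class DegenerateSignalError(EegStressError, ValueError):
    """A signal is constant (or its derivative is), so variance-based
    features are undefined."""


class SignalLengthError(EegStressError, ValueError):
    """A signal is too short for the requested operation."""


class ResolutionError(EegStressError, ValueError):
    """A requested frequency band is not representable on the dyadic
    wavelet-packet grid for the given sampling rate."""


class DatasetError(EegStressError, ValueError):
    """A dataset violates a structural requirement (e.g. a class with no
    usable rows)."""
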