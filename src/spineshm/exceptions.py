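"""Exception hierarchy for the spineshm pipeline."""


class SpineSHMError(Exception):
    """Base class for all spineshm errors."""


class ConfigurationError(SpineSHMError, ValueError):
    """Invalid configuration: bad band, sampling rate, kernel size, model parameters."""


class EstimationError(SpineSHMError, RuntimeError):
    """Spectral estimation cannot proceed (e.g. zero input power, coherence undefined)."""


class AnalysisError(SpineSHMError, RuntimeError):
    """Cohort/twin analysis cannot proceed (e.g. no sensors pass QC, no overlapping sensors)."""


class FormatError(SpineSHMError, ValueError):
    """A file does not match the expected on-disk format."""
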