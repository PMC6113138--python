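"""Shared exception types for the analysis stages."""


class ParameterError(ValueError):
    """Invalid analysis parameter (window, threshold, band, ...)."""


class AnalysisError(RuntimeError):
    """The requested analysis cannot be carried out on these data."""


class FormatError(IOError):
    """A file does not conform to the expected on-disk format."""
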