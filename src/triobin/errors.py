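"""Exception types shared across the pipeline stages."""


class TriobinError(Exception):
    """Base class for all package errors."""


class ConfigurationError(TriobinError):
    """Invalid or inconsistent stage parameters (caught before computation)."""


class SpectrumSignalError(TriobinError):
    """A k-mer spectrum carries no usable signal peak (mirrors 'fail' rows)."""


class UndefinedMetricError(TriobinError):
    """A metric has no defined value on this input (e.g. zero denominators)."""
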