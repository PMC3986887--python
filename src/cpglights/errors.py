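"""Exception hierarchy shared across the package."""


class CpglightsError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(CpglightsError):
    """Invalid configuration or parameter values."""


class MappingError(CpglightsError):
    """A sample column has no entry in the sample/class map."""


class NormalizationError(CpglightsError):
    """RLE normalization has no reference cluster positive in all samples."""


class InsufficientDataError(CpglightsError):
    """Too few observations for the requested statistic."""


class DegenerateModelError(CpglightsError):
    """A motif model whose score distribution cannot attain the target P-value."""


class InputError(CpglightsError):
    """Malformed input such as a non-ACGT character in a word."""


class PipelineError(CpglightsError):
    """A pipeline stage failed; the message names the stage."""
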