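"""Exception hierarchy shared across the package."""


class HccorrectError(Exception):
    """Base class for all package-specific errors."""


class InputFormatError(HccorrectError, ValueError):
    """Malformed input data (bad alphabet, unknown reference name, bad CIGAR...)."""


class ContractViolationError(HccorrectError, ValueError):
    """A caller broke a documented precondition (mismatched lengths, bad coordinates...)."""


class ConfigurationError(HccorrectError, ValueError):
    """Invalid pipeline configuration (bad parameter value, missing placeholder...)."""


class PipelineError(HccorrectError, RuntimeError):
    """A pipeline stage failed at run time (e.g. the external aligner exited non-zero)."""
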