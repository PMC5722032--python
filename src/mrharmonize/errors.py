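"""Exception hierarchy shared across the package."""


class MRHarmonizeError(Exception):
    """Base class for all package-specific errors."""


class FormatError(MRHarmonizeError):
    """A summary or proxy table violates the expected file structure."""


class ValidationError(MRHarmonizeError):
    """A record or dataset violates the data-model invariants."""


class HarmonizationError(MRHarmonizeError):
    """The harmonization pipeline cannot proceed (e.g. nothing survives)."""


class ProxyError(MRHarmonizeError):
    """An LD-proxy substitution is impossible or underdetermined."""


class QCError(MRHarmonizeError):
    """A quality-control statistic is undefined on the given inputs."""


class EstimationError(MRHarmonizeError):
    """A causal estimator's preconditions are not met."""
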