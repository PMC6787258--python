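"""Exception hierarchy for the bucklesense pipeline."""


class BuckleSenseError(Exception):
    """Base class for all package-specific errors."""


class DomainError(BuckleSenseError, ValueError):
    """Input outside the mathematical domain of an operation."""


class AlignmentError(BuckleSenseError):
    """Membrane frame could not be aligned to the analytic buckle."""


class MappingError(BuckleSenseError):
    """Protein position could not be mapped onto the buckle surface."""


class OrientationError(BuckleSenseError):
    """Protein principal axis is undefined (degenerate point cloud)."""


class DegenerateFitError(BuckleSenseError):
    """Circle fit attempted on (near-)collinear points."""


class ConfigError(BuckleSenseError, ValueError):
    """Invalid generator or pipeline configuration."""


class PipelineError(BuckleSenseError):
    """Too many per-frame failures for the result to be trustworthy."""
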