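"""Exception hierarchy shared across the pipeline."""


class DDKAugError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(DDKAugError, ValueError):
    """A configuration or parameter value is invalid; the message names the field."""


class ShapeError(DDKAugError, ValueError):
    """An array does not have the shape a stage requires."""


class DataError(DDKAugError, ValueError):
    """Input data violate a contract (empty set, missing segments, bad manifest)."""


class DegenerateInputError(DDKAugError, ValueError):
    """An input is degenerate for the requested operation (e.g. all-zero signal)."""


class ArchitectureError(DDKAugError, ValueError):
    """A model configuration is internally inconsistent or collapses spatially."""


class LeakageError(DDKAugError, RuntimeError):
    """Subject overlap between partitions that must be disjoint."""


class MetricError(DDKAugError, ValueError):
    """A metric is undefined for the given confusion matrix; the message names it."""
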