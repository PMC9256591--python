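"""Exception hierarchy shared across the toolkit."""


class BarcodekitError(Exception):
    """Base class for all toolkit errors."""


class AlignmentError(BarcodekitError):
    """Malformed alignment (unequal lengths, empty file, bad symbols)."""


class ReconciliationError(BarcodekitError):
    """Sequence ids and metadata rows do not match one-to-one."""


class PartitionError(BarcodekitError):
    """Invalid MOTU partition (duplicate specimens, unknown specimens)."""


class TreeError(BarcodekitError):
    """Malformed or unsuitable tree input."""


class UndefinedDistanceError(BarcodekitError):
    """A pairwise distance has no comparable sites."""


class SaturatedDistanceError(BarcodekitError):
    """Saturated (infinite) distances present where finite ones are required."""


class DegenerateInputError(BarcodekitError):
    """Input carries no usable signal for the requested analysis."""


class ParameterError(BarcodekitError):
    """Invalid user-supplied parameter value."""
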