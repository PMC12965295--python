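"""Exception types shared across the pipeline."""


class PigmentEETError(Exception):
    """Base class for all package-specific errors."""


class ParseError(PigmentEETError):
    """A coordinate file could not be read."""


class FormatError(PigmentEETError):
    """Unknown or unsupported coordinate file format."""


class DegeneratePigmentError(PigmentEETError):
    """A pigment instance lacks the atoms required for the requested descriptor."""


class GeometryError(PigmentEETError):
    """Degenerate geometry (collinear ring atoms, coincident anchors, ...)."""


class GroupingError(PigmentEETError):
    """A network node has no subunit assignment."""


class ConditioningError(PigmentEETError):
    """A linear system is rank-deficient (e.g. duplicate lifetimes)."""


class PackingError(PigmentEETError):
    """Rejection sampling could not satisfy the minimum-separation constraint."""


class ParameterError(PigmentEETError):
    """Invalid generator or model parameters."""
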