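"""Exception hierarchy for fractalarbor."""


class FractalArborError(Exception):
    """Base class for all package-specific errors."""


class SWCFormatError(FractalArborError, ValueError):
    """Malformed SWC content (bad line, bad field)."""


class StructureError(FractalArborError, ValueError):
    """Arbor topology is not a rooted tree (cycle, missing parent, ...)."""


class MeshFormatError(FractalArborError, ValueError):
    """Malformed mesh file (e.g. face index out of range)."""


class ParameterError(FractalArborError, ValueError):
    """Invalid parameter value passed to an operation."""


class InsufficientScalingRangeError(FractalArborError, RuntimeError):
    """The admissible box-size window spans less than one decade."""


class DegenerateGeometryError(FractalArborError, RuntimeError):
    """Geometry too degenerate for the requested metric (e.g. coplanar hull)."""
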