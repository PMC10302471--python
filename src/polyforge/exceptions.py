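"""Exception hierarchy.

All user-facing errors derive from :class:`PolyforgeError` so callers (and the
CLI) can distinguish validation failures from genuine bugs.
"""


class PolyforgeError(ValueError):
    """Base class for all validation and build errors."""


class ParseError(PolyforgeError):
    """A structure source could not be parsed in the stated format."""


class DecorationError(PolyforgeError):
    """A monomer is missing (or mis-uses) its placeholder decoration."""


class StructureError(PolyforgeError):
    """A graph edit violates structural preconditions (degree, coords, ...)."""


class TopologyError(PolyforgeError):
    """A builder's topological preconditions are not met."""


class ProbabilityError(PolyforgeError):
    """A composition probability lies outside its valid range."""


class MinimizationError(PolyforgeError):
    """No force field could be typed for the molecule."""


class EngineError(PolyforgeError):
    """An unknown external calculator engine was requested."""
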