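"""Exception hierarchy.

All library errors derive from :class:`BicnetError` so callers (and the CLI)
can distinguish usage/data problems from genuine bugs.
"""


class BicnetError(Exception):
    """Base class for all bicnet errors."""


class InvalidArgumentError(BicnetError, ValueError):
    """An argument violates a documented precondition."""


class InvalidValueError(BicnetError, ValueError):
    """A data value is outside its declared domain (e.g. discrete level)."""


class CyclicStructureError(BicnetError):
    """A graph that must be acyclic contains a directed cycle."""


class MixedConstraintError(BicnetError):
    """A discrete child was given a continuous parent."""


class UnsupportedCombinationError(BicnetError):
    """A configuration combination the method does not define.

    Scale-free topology is only defined for all-continuous networks: growing a
    discrete scale-free network would let hub children accumulate unbounded
    parent sets and blow up their conditional tables.
    """


class InsufficientDataError(BicnetError):
    """Too few rows to fit the requested family."""


class DataFormatError(BicnetError):
    """A file could not be parsed under the declared format."""


class SimulationError(BicnetError):
    """The simulator could not satisfy its own constraints (e.g. CPT rejection cap)."""
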