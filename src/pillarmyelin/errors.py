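"""Exception hierarchy.

``ValidationError`` covers bad inputs caught before computation (CLI exit
code 2); ``ComputationError`` covers failures discovered during a stage
(CLI exit code 3).
"""


class PillarMyelinError(Exception):
    """Base class for all package errors."""


class ValidationError(PillarMyelinError, ValueError):
    """Invalid parameter or input rejected before any computation."""


class GeometryError(ValidationError):
    """Requested geometry does not fit (e.g. grid larger than the field)."""


class ComputationError(PillarMyelinError, RuntimeError):
    """A pipeline stage failed on otherwise valid input."""


class GridNotFoundError(ComputationError):
    """Too few pillars detected to fit a lattice."""


class NoContactError(ComputationError):
    """Force curve contains no detectable contact region."""


class InsufficientDataError(ComputationError):
    """Not enough usable samples for a fit."""


class DegenerateDataError(ComputationError):
    """Statistical input is degenerate (single group, zero variance, ...)."""
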