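"""Exception hierarchy for steppefav.

Every stage raises a specific subclass of :class:`SteppefavError` so that the
pipeline driver can abort with the stage name and a useful message instead of a
bare traceback.
"""


class SteppefavError(Exception):
    """Base class for all package errors."""


class InvalidConfigError(SteppefavError):
    """A configuration value violates an invariant (e.g. non-divisible cell sizes)."""


class PlacementError(SteppefavError):
    """Census points could not be placed at the required minimum spacing."""


class ReclassificationError(SteppefavError):
    """A raw land-cover code has no entry in the reclassification map."""


class BoundaryError(SteppefavError):
    """A buffer extends beyond the land-cover grid; no silent truncation."""


class DegenerateVariableError(SteppefavError):
    """A candidate variable has zero variance and cannot be standardized."""


class SeparationError(SteppefavError):
    """Logistic fit failed to converge, typically complete separation."""


class UndefinedDiversityError(SteppefavError):
    """Shannon index requested for an all-zero composition vector."""


class UndefinedAUCError(SteppefavError):
    """AUC requested when only one response class is present."""


class SchemaError(SteppefavError):
    """An input table or grid is missing required columns or violates invariants."""


class NonConvergenceError(SteppefavError):
    """An iterative fit did not converge; message carries diagnostics."""
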