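"""Exception hierarchy shared across the package."""


class FosnetError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(FosnetError):
    """Input table does not match the declared region scheme."""


class LabelError(FosnetError):
    """A group label is not in the declared label set."""


class CountValueError(FosnetError, ValueError):
    """A count cell is negative or non-numeric."""


class StateError(FosnetError):
    """Operation applied to an object in the wrong state (e.g. double normalization)."""


class DegenerateControlError(FosnetError):
    """Control group mean is zero for some region; normalization undefined."""


class UndefinedIndexError(FosnetError, ZeroDivisionError):
    """Generalization index undefined because total freezing is zero."""


class DegenerateVarianceError(FosnetError):
    """A region has zero variance within a group; Pearson r undefined."""


class ConstructionError(FosnetError):
    """Requested correlation structure is not positive semidefinite."""


class UndefinedSDError(FosnetError):
    """Fewer than two pooled values; sample SD undefined."""


class DomainError(FosnetError, ValueError):
    """Parameter outside its legal domain (e.g. non-positive edge weight)."""


class UnreachableTargetError(FosnetError):
    """Clustering target exceeds the zero-rewiring lattice value."""


class UndefinedModularityError(FosnetError):
    """Modularity undefined for an edgeless network."""


class ConvergenceWarning(UserWarning):
    """Iterative search terminated without meeting its tolerance."""
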