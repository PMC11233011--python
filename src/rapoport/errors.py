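"""Exception types shared across the package."""


class RapoportError(Exception):
    """Base class for all package-specific errors."""


class InsufficientRecordsError(RapoportError):
    """Too few (or degenerate) occurrence records to build a range polygon."""


class InsufficientDataError(RapoportError):
    """Not enough shared observations for a comparison."""


class AlphaSearchError(RapoportError):
    """The dynamic alpha search did not converge within the iteration budget."""


class ProjectionDomainError(RapoportError):
    """Coordinates or parameters outside the projection's valid domain."""


class DegenerateInputError(RapoportError):
    """Input carries no usable variation (e.g. a constant vector)."""


class RankDeficiencyError(RapoportError):
    """Design matrix is singular; offending columns are reported."""

    def __init__(self, message, columns=()):
        super().__init__(message)
        self.columns = tuple(columns)


class LabelsMismatchError(RapoportError):
    """Data labels and tree tip labels do not match one-to-one."""

    def __init__(self, message, missing_in_tree=(), missing_in_data=()):
        super().__init__(message)
        self.missing_in_tree = tuple(missing_in_tree)
        self.missing_in_data = tuple(missing_in_data)


class InvalidTreeError(RapoportError):
    """Phylogeny violates a structural requirement (e.g. covariance not PSD)."""


class ConvergenceError(RapoportError):
    """An iterative fit failed to converge or left its admissible domain."""


class CombinatorialLimitError(RapoportError):
    """All-subsets model enumeration refused for too many predictors."""


class GenerationFailureError(RapoportError):
    """Synthetic-range generation could not honour the requested geometry."""


class PlacementFailureError(RapoportError):
    """Spreading-dye placement exhausted its restart budget for a species."""


class NullDistributionUnstableError(RapoportError):
    """Too many null-model replicates failed to fit."""


class SchemaError(RapoportError):
    """Input file does not match the expected column schema."""


class NewickParseError(RapoportError):
    """Malformed Newick input."""
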