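"""Exception hierarchy for hydromap.

All domain errors derive from :class:`HydromapError` so callers can catch the
package's failures with a single except clause while letting programming
errors (TypeError etc.) propagate.
"""


class HydromapError(Exception):
    """Base class for all hydromap domain errors."""


class InvalidArgumentError(HydromapError, ValueError):
    """A parameter value violates an operation's contract."""


class InvalidTreeError(HydromapError):
    """Tree lacks required structure (e.g. branch lengths)."""


class MissingTaxonError(HydromapError):
    """Requested taxa absent from the tree; carries the offending labels."""

    def __init__(self, missing, message=None):
        self.missing = sorted(missing)
        super().__init__(message or f"taxa not found in tree: {self.missing}")


class DegenerateDataError(HydromapError):
    """Trait data carry no variance (or too few values) for the statistic."""


class IllConditionedTreeError(HydromapError):
    """Phylogenetic covariance matrix is singular or near-singular."""


class InsufficientDataError(HydromapError):
    """Not enough observations/groups after filtering to run the test."""


class EmptySubsetError(InsufficientDataError):
    """A replication filter removed every record."""


class UnfillablePlotError(HydromapError):
    """No record in a plot is resolvable at any taxonomic level."""


class UndefinedCoverageError(HydromapError):
    """Plot has zero dicot basal area; coverage fraction undefined."""


class InvalidMatrixError(InvalidArgumentError):
    """Dissimilarity matrix is not symmetric/square/zero-diagonal."""


class InvalidFoldsError(InvalidArgumentError):
    """Cross-validation folds are degenerate (empty, or one fold holds all points)."""


class SaturatedModelError(HydromapError):
    """ANOVA model leaves zero residual degrees of freedom."""


class PipelineValidationError(HydromapError):
    """Input validation failed; carries the itemised report."""

    def __init__(self, issues):
        self.issues = list(issues)
        lines = "; ".join(str(i) for i in self.issues)
        super().__init__(f"validation failed: {lines}")


class PipelineDependencyError(HydromapError):
    """A pipeline stage was enabled without the stage that produces its input."""
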