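"""Exception hierarchy for corrclust."""


class CorrclustError(Exception):
    """Base class for all corrclust errors."""


class MatrixValidationError(CorrclustError, ValueError):
    """An input matrix violates a structural invariant (symmetry, diagonal, range)."""


class ZeroVarianceError(CorrclustError, ValueError):
    """A time-series column has zero variance, so its correlations are undefined."""


class IllConditionedError(CorrclustError, ValueError):
    """Covariance/correlation matrix is singular or too ill-conditioned to invert."""


class DegenerateTripleError(CorrclustError, ValueError):
    """A conditioning node is (numerically) a perfect copy of a neighbour, so the
    three-way partial correlation or partial mutual information is undefined."""


class HQSPreconditionError(CorrclustError, ValueError):
    """The H-Q-S moment preconditions fail (mean off-diagonal covariance <= 0, or
    zero off-diagonal variance)."""


class UndefinedGlobalError(CorrclustError, ValueError):
    """No node has a defined local coefficient, so the global average is undefined."""
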