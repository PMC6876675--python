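"""Exception hierarchy for the ipwdid package."""


class IPWDIDError(Exception):
    """Base class for all package errors."""


class ValidationError(IPWDIDError):
    """Input data violates a schema or range contract."""


class DegenerateSelectionError(IPWDIDError):
    """Realized treatment assignment left one arm empty."""

    def __init__(self, treated_share: float):
        self.treated_share = treated_share
        super().__init__(
            f"degenerate selection: realized treated share is {treated_share:.4f}; "
            "both arms must be non-empty"
        )


class SeparationError(IPWDIDError):
    """Probit likelihood is unbounded due to perfect separation."""

    def __init__(self, covariate: str | None = None):
        self.covariate = covariate
        name = covariate if covariate is not None else "<not identified>"
        super().__init__(f"perfect separation detected (separating covariate: {name})")


class ConvergenceError(IPWDIDError):
    """Maximum-likelihood optimisation failed to meet the gradient tolerance."""


class DisjointSupportError(IPWDIDError):
    """Treated and control propensity-score ranges do not overlap."""


class EstimationError(IPWDIDError):
    """Regression stage failed (singular design, constant outcome, too few clusters)."""
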