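"""Exception hierarchy for sumshare."""


class SumShareError(ValueError):
    """Base class for all sumshare-specific errors."""


class ValidationError(SumShareError):
    """Input data violates a structural precondition (shape, coding, labels)."""


class DegenerateDataError(SumShareError):
    """Data carries no information for the requested fit or test
    (constant outcome, constant predictor, empty input)."""


class SingularVarianceError(SumShareError):
    """The score variance matrix V is singular, so T = S V^-1 S' is undefined.

    Typical causes: a monomorphic SNP (no genotype variation), a constant
    phenotype column, or two perfectly collinear phenotypes.  Passing
    ``pseudo_inverse=True`` to the test computes a rank-reduced statistic
    instead of raising.
    """


class SchemaError(SumShareError):
    """A summary-exchange document does not conform to the expected schema."""
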