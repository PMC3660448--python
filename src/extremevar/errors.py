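"""Exception hierarchy for the pipeline."""


class ExtremevarError(Exception):
    """Base class for all package errors."""


class VCFParseError(ExtremevarError):
    """Raised when a VCF record cannot be parsed or violates preconditions."""


class UndefinedFrequencyError(ExtremevarError):
    """Raised when an allele frequency is requested from all-missing calls."""


class DesignError(ExtremevarError):
    """Raised for invalid phenotype/covariate inputs or degenerate strata."""


class AssociationError(ExtremevarError):
    """Raised when an association test's preconditions are not met."""
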