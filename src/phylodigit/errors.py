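"""Exception hierarchy for phylodigit.

All package errors derive from :class:`PhylodigitError` so callers can catch
everything the pipeline may raise with a single except clause.
"""


class PhylodigitError(Exception):
    """Base class for all phylodigit errors."""


class NewickParseError(PhylodigitError):
    """Malformed newick input; the message names the offending position."""


class TreeValidationError(PhylodigitError):
    """Tree violates a structural invariant (duplicate tips, bad root, ...)."""


class BranchLengthError(PhylodigitError):
    """Branch lengths missing, negative, or otherwise unusable."""


class DataError(PhylodigitError):
    """Input data missing, mismatched, or outside its documented domain."""


class KeyingError(DataError):
    """Species keys do not resolve across data sources; lists the offenders."""


class DegenerateNodeError(PhylodigitError):
    """A contrast node has zero total adjusted branch length."""


class UndefinedStatisticError(PhylodigitError):
    """A statistic is undefined for the given input (zero variance etc.)."""


class LinearAlgebraError(PhylodigitError):
    """A matrix required to be invertible / positive definite is not."""


class DegenerateLikelihoodError(PhylodigitError):
    """The ML error variance is zero; the likelihood is unbounded."""


class ConfigurationError(PhylodigitError):
    """Unknown method name or invalid configuration value."""
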