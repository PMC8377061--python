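"""Exception hierarchy for gsemkit.

All package-specific failures derive from :class:`GsemError` so callers can
catch one base class at pipeline boundaries.
"""


class GsemError(Exception):
    """Base class for all gsemkit errors."""


class ValidationError(GsemError):
    """A domain object violates one of its invariants."""


class MalformedFileError(GsemError):
    """A binary or text input does not match the expected layout."""


class MissingCompanionError(GsemError):
    """A multi-file artifact is missing a required companion file."""


class EmptyPanelError(GsemError):
    """No SNPs remain after filtering."""


class NumericalDegeneracyError(GsemError):
    """A quantity required for standardization or scaling is zero."""


class CollinearityError(GsemError):
    """A covariate design matrix is rank deficient."""


class DegenerateRankError(GsemError):
    """A vector cannot be rank-transformed (all values tied)."""


class NoOverlapError(GsemError):
    """Phenotype and GRM individual sets do not intersect."""


class IdentificationError(GsemError):
    """A factor structure is not identified for the given trait count."""


class ConditioningError(GsemError):
    """A matrix is too ill-conditioned to proceed."""


class ConvergenceError(GsemError):
    """No optimization start reached a usable optimum."""


class NotApplicableError(GsemError):
    """An operation was requested for a model it is not defined for."""


class DatasetMismatchError(GsemError):
    """Model-comparison inputs were not fitted on the same dataset."""
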