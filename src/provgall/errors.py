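"""Exception hierarchy for provgall.

Every error raised deliberately by the package derives from
:class:`ProvgallError`, so callers (and the CLI) can separate user/data
problems from genuine bugs.
"""


class ProvgallError(Exception):
    """Base class for all provgall errors."""


class InvalidDesignError(ProvgallError):
    """Trial design violates a structural constraint (e.g. < 2 provenances)."""


class InvalidParameterError(ProvgallError):
    """A simulation or model parameter is outside its valid range."""


class InvalidCoordinateError(ProvgallError):
    """Latitude/longitude outside [-90, 90] / [-180, 180]."""


class UndefinedPairError(ProvgallError):
    """A provenance pair shares no genotyped locus, so theta is undefined."""


class UndefinedCorrelationError(ProvgallError):
    """Mantel correlation undefined because a matrix has zero variance."""


class UnderdeterminedFitError(ProvgallError):
    """Too few pairs to fit the differentiation-vs-distance regression."""


class StructureError(ProvgallError):
    """A covariance structure is not usable (wrong size, not PSD)."""


class ConfigurationError(ProvgallError):
    """Inconsistent or incomplete run configuration."""


class SchemaError(ProvgallError):
    """An input table is missing required columns or fails validation."""


class DuplicateRecordError(SchemaError):
    """Duplicate (tree, shoot, year, season, gall_type) survey key."""


class ScheduleError(ProvgallError):
    """MCMC schedule leaves too few retained draws."""


class DegenerateDataError(ProvgallError):
    """Data degenerate for the requested model (e.g. zero-variance response)."""


class ContractError(ProvgallError):
    """Posterior object does not satisfy an operation's preconditions."""


class AliasingError(ProvgallError):
    """Perfectly collinear fixed-effect columns."""

    def __init__(self, aliased, message=None):
        self.aliased = list(aliased)
        super().__init__(message or f"aliased fixed-effect columns: {self.aliased}")
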