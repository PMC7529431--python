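"""Exception taxonomy for famburden."""


class FamburdenError(Exception):
    """Base class for all famburden errors."""


class ParseError(FamburdenError):
    """A file could not be parsed; the message names the offending line."""


class PloidyError(ParseError):
    """A genotype call is not diploid."""


class ValidationError(FamburdenError):
    """An in-memory object violates its invariants."""


class ConfigurationError(FamburdenError):
    """A configuration value is inconsistent or refers to an unknown entity."""


class UndefinedKinshipError(FamburdenError):
    """The KING-robust denominator is zero for a sample pair."""


class SeparationError(FamburdenError):
    """The null logistic model is perfectly separated by a covariate."""


class ConvergenceError(FamburdenError):
    """An iterative fit or numerical integration failed to converge."""


class DegenerateStatisticError(FamburdenError):
    """A test statistic is undefined (e.g. all variants monomorphic)."""
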