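"""Exception hierarchy for the threathelp pipeline."""


class ThreathelpError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(ThreathelpError):
    """Invalid parameters, malformed tables, or inconsistent designs."""


class DegenerateTrialError(ThreathelpError):
    """A trial's voxel vector is constant, so its pattern correlation is undefined."""


class LabelMismatchError(ThreathelpError):
    """Two RDMs do not share the same set of trial labels."""


class CollinearityError(ThreathelpError):
    """A linear-model design matrix is rank deficient."""


class UndefinedStatisticError(ThreathelpError):
    """A statistic has no defined value for the given input (e.g. tau-b with all ties)."""


class InsufficientDataError(ThreathelpError):
    """Too few observations to run the requested test."""
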