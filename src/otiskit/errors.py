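"""Exception types shared across the package."""


class OtiskitError(Exception):
    """Base class for all package errors."""


class InfeasiblePreset(OtiskitError):
    """A generative preset implies a negative residual variance or an
    out-of-range probability and cannot be simulated from."""


class MissingVisit(OtiskitError):
    """An infant lacks one of the four scheduled dietary records; cumulative
    intake is undefined for them (they are excluded, never imputed)."""


class EmptyFrame(OtiskitError):
    """No listwise-complete rows survive frame construction."""


class SEMError(OtiskitError):
    """Base class for structural-equation-model errors."""


class UnknownVariable(SEMError):
    pass


class DuplicatePath(SEMError):
    pass


class CycleDetected(SEMError):
    pass


class SingularSystem(SEMError):
    """(I - B) is not invertible for the supplied parameters."""


class NonPDSample(SEMError):
    """The sample covariance matrix is not positive definite."""


class NonConvergence(SEMError):
    """The discrepancy-function gradient did not fall below tolerance."""


class RankDeficientScores(SEMError):
    """The casewise score matrix is rank deficient; the sandwich covariance
    is undefined."""
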