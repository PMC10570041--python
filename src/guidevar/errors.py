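"""Exception hierarchy shared across the package."""


class GuideVarError(Exception):
    """Base class for all package-specific errors."""


class AlphabetError(GuideVarError):
    """Sequence contains a character outside the allowed alphabet."""


class LengthError(GuideVarError):
    """Spacer length outside the supported 19-20 nt range."""


class LengthMismatchError(GuideVarError):
    """Two paired sequences (or vectors) differ in length."""


class MissingIdError(GuideVarError):
    """An sgRNA id expected in one table is absent from another."""


class DegenerateReferenceError(GuideVarError):
    """Reference population has zero variance; Z-scores undefined."""


class DegenerateError(GuideVarError):
    """Both group variances are zero; effect size undefined."""


class RangeError(GuideVarError):
    """Numeric input outside its documented range."""


class CompositionError(GuideVarError):
    """Mismatch panel composition not realizable for the spacer length."""


class ZeroDenominatorError(GuideVarError):
    """Ratio denominator is zero and no pseudocount was supplied."""


class EmptyInputError(GuideVarError):
    """An estimator received no usable records."""


class MismatchCountError(GuideVarError):
    """Guide-target pair has the wrong number of mismatches for this operation."""


class MissingParameterError(GuideVarError):
    """A required thermodynamic parameter is absent from the table."""


class InsufficientDataError(GuideVarError):
    """Too few records to compute the requested statistic."""


class InsufficientGroupError(GuideVarError):
    """A triage category has fewer than two sgRNAs in one arm."""


class FrozenViolationError(GuideVarError):
    """A frozen encoder's parameters changed during fine-tuning."""


class UncalibratedModelError(GuideVarError):
    """Model used for prediction before calibration bounds were stored."""


class UnknownKindError(GuideVarError):
    """Unrecognized regressor kind."""


class ConvergenceWarning(UserWarning):
    """Training loss stopped improving before the epoch budget was reached."""


class SchemaError(GuideVarError):
    """A tabular input file violates its declared schema."""


class CapacityError(GuideVarError):
    """Toy genome too small to hold the requested planted sites."""


class ConfigError(GuideVarError):
    """Run configuration invalid; message names the offending key."""
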