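"""Exception hierarchy.

Clinical features that were not assessed are *absent*, never silently
false; any score that depends on an absent feature raises
:class:`ComputabilityError` instead of defaulting, so that sensitivity
and specificity estimates cannot be corrupted by imputed negatives.
"""


class KidsmsError(Exception):
    """Base class for all errors raised by this package."""


class SchemaError(KidsmsError):
    """A cohort CSV does not match the documented column schema."""


class RowParseError(KidsmsError):
    """A cell of a cohort CSV could not be parsed.

    Carries the 1-based data-row number in :attr:`row`.
    """

    def __init__(self, row: int, message: str):
        self.row = row
        super().__init__(f"row {row}: {message}")


class ComputabilityError(KidsmsError):
    """A score was requested for a record missing a required feature."""


class CovariateRangeError(KidsmsError):
    """A nomogram was evaluated outside its admissible covariate range."""
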