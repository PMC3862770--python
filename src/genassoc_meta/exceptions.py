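"""Exception hierarchy for the meta-analysis pipeline."""


class GenassocError(Exception):
    """Base class for all package errors."""


class SchemaError(GenassocError):
    """The input table is structurally unusable (e.g. a mandatory column is absent)."""


class ValidationError(GenassocError):
    """One or more rows violate the record invariants.

    Carries per-row diagnostics so a user can fix the offending rows in one pass.
    """

    def __init__(self, problems):
        self.problems = list(problems)
        super().__init__(
            "%d invalid row(s):\n%s" % (len(self.problems), "\n".join(self.problems))
        )


class EligibilityError(GenassocError):
    """A study lacks the counts required for the requested genetic model."""


class NonInformativeStudyError(GenassocError):
    """All four cells of a 2x2 table are zero; the study carries no information."""


class InsufficientStudiesError(GenassocError):
    """Fewer studies than the procedure's minimum (e.g. Egger needs k >= 3)."""


class SingularDesignError(GenassocError):
    """A regression design matrix is rank-deficient (e.g. identical precisions)."""
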