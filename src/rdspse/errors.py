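"""Named exception types for RDS data validation and model fitting."""


class RDSValidationError(ValueError):
    """Base class for invalid RDS recruitment data."""


class MissingColumnError(RDSValidationError):
    """A required column could not be resolved in the input file."""


class DuplicateIdError(RDSValidationError):
    """Two participants share the same identifier."""


class CyclicRecruitmentError(RDSValidationError):
    """Recruitment links contain a cycle (not a forest rooted at seeds)."""


class RecruitmentOrderError(RDSValidationError):
    """A recruiter is enrolled at or after one of their recruits."""


class DegreeInconsistencyError(RDSValidationError):
    """degree_seen exceeds degree_known on some row."""


class PriorInfeasibleError(ValueError):
    """The prior on N cannot be constructed (e.g. prior median below n)."""


class ModelError(RuntimeError):
    """Non-recoverable failure during model fitting."""
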