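"""Exception hierarchy for atsdnet."""


class AtsdnetError(Exception):
    """Base class for all atsdnet errors."""


class SchemaError(AtsdnetError):
    """The input table does not match the declared column schema."""


class ValidationError(AtsdnetError):
    """A dataset value violates an invariant (non-positive abundance,
    duplicate sample, unknown time point, ...)."""


class DesignError(AtsdnetError):
    """A stage design is internally inconsistent or incompatible with the
    dataset (non-contiguous stage, empty analysis window, ...)."""


class InsufficientDataError(AtsdnetError):
    """Too few samples to compute the requested statistic."""
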