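"""Exception hierarchy for cohort and clock validation failures."""


class PyroclockError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(PyroclockError, ValueError):
    """A table or document is missing a required column/field or has an unknown key."""


class IntegrityError(PyroclockError, ValueError):
    """Cross-record consistency violated (e.g. duplicate sample ids)."""


class ValidationError(PyroclockError, ValueError):
    """A field value violates its domain constraints."""


class ConfigError(PyroclockError, ValueError):
    """A generator or run configuration is invalid."""


class SingularDesignError(PyroclockError, ValueError):
    """The regression design matrix is rank deficient."""


class InsufficientDataError(PyroclockError, ValueError):
    """Too few samples for the requested fit or summary."""


class MissingSiteError(PyroclockError, KeyError):
    """A profile lacks a methylation value required by a clock."""


class FoldSizeError(PyroclockError, ValueError):
    """A cross-validation fold layout cannot support the model size."""
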