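"""Error hierarchy.

Every exception carries a stable ``code`` string so callers (and the CLI) can
match on machine-readable identifiers instead of messages.
"""

from __future__ import annotations


class ModelError(Exception):
    """Base class for all model-level errors."""

    code = "E_MODEL"

    def __init__(self, message: str = "", subject: str | None = None):
        self.subject = subject
        if subject and subject not in message:
            message = f"{message} [{subject}]" if message else subject
        super().__init__(f"{self.code}: {message}")


class NoSuchPropertyError(ModelError):
    """A (domain, category) pair with no registered property class."""

    code = "E_NO_SUCH_PROPERTY"


class UnresolvedRefError(ModelError):
    code = "E_UNRESOLVED_REF"


class DuplicateIdError(ModelError):
    code = "E_DUPLICATE_ID"


class MissingRoleError(ModelError):
    code = "E_MISSING_ROLE"


class BadConstitutiveError(ModelError):
    """Constitutive parameter outside its admissible range (e.g. R <= 0)."""

    code = "E_BAD_CONSTITUTIVE"


class NegativeStateError(ModelError):
    code = "E_NEGATIVE_STATE"


class BadStateError(ModelError):
    code = "E_BAD_STATE"


class NoInitialValueError(ModelError):
    code = "E_NO_INITIAL"


class OverdeterminedError(ModelError):
    code = "E_OVERDETERMINED"


class UnderdeterminedError(ModelError):
    code = "E_UNDERDETERMINED"


class AlgebraicLoopError(ModelError):
    """A cycle of algebraic dependencies with no storage element in between."""

    code = "E_ALGEBRAIC_LOOP"

    def __init__(self, message: str = "", cycle: list[str] | None = None):
        self.cycle = list(cycle or [])
        super().__init__(message or " -> ".join(self.cycle))


class NotCompiledError(ModelError):
    code = "E_NOT_COMPILED"


class DivergedError(ModelError):
    code = "E_DIVERGED"


class NoSteadyStateError(ModelError):
    code = "E_NO_STEADY_STATE"


class NonConstantSourceError(ModelError):
    code = "E_NONCONSTANT_SOURCE"


class ParseError(ModelError):
    code = "E_PARSE"


class SchemaError(ModelError):
    code = "E_SCHEMA"


class NoIriError(ModelError):
    code = "E_NO_IRI"
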