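"""Typed exceptions raised by the repository engine."""


class ScreenbankError(Exception):
    """Base class for all package errors."""


class ReferentialError(ScreenbankError):
    """A referenced entity id does not resolve."""


class ConflictError(ScreenbankError):
    """A unique key (id, pseudonym, series UID) is already taken."""


class CardinalityError(ScreenbankError):
    """A relation's multiplicity contract is violated."""


class ChronologyError(ScreenbankError):
    """A cause event is dated after one of its effects."""


class CycleError(ScreenbankError):
    """Adding an implication would make the cause-effect graph cyclic."""


class DomainError(ScreenbankError):
    """A scalar argument is outside its valid domain."""


class ConsistencyError(ScreenbankError):
    """Input files disagree on an invariant (e.g. mixed patient ids)."""


class DeidRequiredError(ScreenbankError):
    """Input still carries direct identifiers and cannot be ingested."""


class GeometryError(ScreenbankError):
    """A mask's grid does not match its source series."""


class WorkflowError(ScreenbankError):
    """A donor timeline is missing a structurally required event."""
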