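"""Exception hierarchy shared across the CoDeL package."""


class CoDeLError(Exception):
    """Base class for all CoDeL errors."""


class ProtocolSyntaxError(CoDeLError):
    """Raised by the protocol parser; carries line/column of the offending token."""

    def __init__(self, message: str, line: int | None = None, column: int | None = None):
        self.line = line
        self.column = column
        loc = f" (line {line}, column {column})" if line is not None else ""
        super().__init__(message + loc)


class UnknownActKind(CoDeLError):
    """An act name outside the eight speech-act kinds was used."""


class UnknownIntervention(CoDeLError):
    """An intervention symbol is not defined in the guideline knowledge base."""


class KBSchemaError(CoDeLError):
    """A knowledge-base file violates the published schema."""


class DanglingAlternative(KBSchemaError):
    """An intervention lists an alternative that is not defined in the same KB."""


class NoAlternativeAvailable(CoDeLError):
    """No admissible substitute exists for a rejected, mandatory intervention."""


class ProtocolViolation(CoDeLError):
    """An agent emitted a message its counterpart's protocol cannot receive."""


class IllegalPair(ProtocolViolation):
    """Two consecutive speech acts form a prohibited interaction pair."""


class GuardFailed(CoDeLError):
    """A clause's guard constraint evaluated false at execution time."""


class NotYourTurn(CoDeLError):
    """A message was emitted by the agent that does not hold the turn."""


class TurnLimitExceeded(CoDeLError):
    """The session exceeded the configured maximum number of messages."""


class IllegalTranscript(CoDeLError):
    """A transcript contains an illegal adjacent speech-act pair."""
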