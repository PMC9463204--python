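"""Exception hierarchy for the cupgrammar package."""


class CupGrammarError(Exception):
    """Base class for all package errors."""


class ParseError(CupGrammarError):
    """A coded sequence could not be tokenized.

    Carries the token index within the sequence and the offending text.
    """

    def __init__(self, message: str, *, position: int, token: str):
        super().__init__(f"{message} (token {position}: {token!r})")
        self.position = position
        self.token = token


class ValidationError(CupGrammarError):
    """A structurally parseable object violates a domain invariant."""


class CanonicalizationError(CupGrammarError):
    """A hand-coded token cannot be reconciled with the tracked state."""

    def __init__(self, message: str, *, index: int):
        super().__init__(f"{message} (event {index})")
        self.index = index


class IllegalMoveError(CupGrammarError):
    """An event is physically impossible from the current workspace state."""


class DomainError(CupGrammarError):
    """An argument is outside the operation's domain (e.g. n_cups < 1)."""


class SchemaError(CupGrammarError):
    """An input table or config file has a missing/invalid schema."""


class ConfigError(CupGrammarError):
    """A simulation or pipeline configuration is invalid."""
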