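"""Exception types shared across the package."""


class InvalidInputError(ValueError):
    """Raised when an input violates a documented precondition or schema."""


class SessionLogError(InvalidInputError):
    """Raised when a serialized session log fails schema validation.

    Carries the 1-based line numbers of the offending records.
    """

    def __init__(self, message: str, bad_lines: list[int] | None = None):
        super().__init__(message)
        self.bad_lines = bad_lines or []
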