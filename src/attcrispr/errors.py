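"""Exception types shared across the package."""


class AttCrisprError(Exception):
    """Base class for package errors."""


class InvalidAlphabetError(AttCrisprError, ValueError):
    """A sequence contains a character outside {A, C, G, T} (or U)."""


class LengthMismatchError(AttCrisprError, ValueError):
    """A sequence does not match the configured model length."""


class MalformedMatrixError(AttCrisprError, ValueError):
    """A one-hot matrix violates its structural invariants."""


class NotFittedError(AttCrisprError, RuntimeError):
    """A model was used before training / loading parameters."""


class SchemaError(AttCrisprError, ValueError):
    """A feature table does not match the schema seen at fit time."""
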