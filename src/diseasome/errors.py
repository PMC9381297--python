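"""Exception hierarchy shared across the pipeline."""


class DiseasomeError(Exception):
    """Base class for all package errors."""


class InputError(DiseasomeError):
    """A user-supplied file is malformed or inconsistent."""


class ValidationError(DiseasomeError):
    """An in-memory object violates a contract (shapes, labels, thresholds)."""
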