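"""Package-wide exception types."""


class ImmersimError(Exception):
    """Base class for all package errors."""


class InvalidTraceError(ImmersimError):
    """An Immersion trace violates the invariants required for metric computation."""


class DegenerateModelError(ImmersimError):
    """A synthesis model cannot be fit (e.g. a constant column)."""


class SchemaMismatchError(ImmersimError):
    """Two tables that must share a schema do not."""
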