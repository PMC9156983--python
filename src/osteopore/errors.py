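"""Exception hierarchy.

All contract violations raise :class:`InputError` (a ``ValueError``) or one of
its narrower subclasses so callers can catch the whole family at once.
"""


class OsteoporeError(Exception):
    """Base class for all package-specific errors."""


class InputError(OsteoporeError, ValueError):
    """A precondition on an argument was violated."""


class DimensionError(InputError):
    """Array shapes or grid geometries are incompatible."""


class SchemaError(InputError):
    """A metrics record is missing required fields."""


class GenerationError(OsteoporeError, RuntimeError):
    """Phantom generation could not satisfy a placement constraint."""
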