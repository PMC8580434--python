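"""Exception hierarchy shared across the package."""


class TentacularError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(TentacularError):
    """A landmark table or manifest violates the expected schema."""


class DegenerateGeometryError(TentacularError):
    """Landmark geometry is degenerate (coincident points, zero-length tentacle)."""


class EmptySampleError(TentacularError):
    """A circular-statistics operation received an empty sample."""


class InsufficientSampleError(TentacularError):
    """Sample too small for the requested analysis (e.g. AICc needs n >= 4)."""
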