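"""Exception hierarchy shared across the analysis modules."""


class ProfilerError(Exception):
    """Base class for all package-specific errors."""


class SpecificationError(ProfilerError):
    """A generator or analysis specification violates its invariants."""


class InputError(ProfilerError):
    """Caller-supplied data are malformed or inconsistent."""


class PlacementError(ProfilerError):
    """Somata could not be placed under the separation constraint."""


class ControlReferenceError(ProfilerError):
    """A control reference stratum is degenerate (n < 2 or zero spread)."""


class ClassificationError(ProfilerError):
    """A z-score could not be mapped to a category (non-finite input)."""


class ModelError(ProfilerError):
    """A statistical model could not be fitted (e.g. singular design)."""


class ConfigError(ProfilerError):
    """A run configuration failed schema validation."""
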