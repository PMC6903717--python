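"""Exception hierarchy shared across the package."""


class SnpccError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(SnpccError, ValueError):
    """An input table violates a field-level invariant."""


class StructuralError(SnpccError, ValueError):
    """The matched-pair structure of a cohort is invalid."""


class NonIdentifiableError(SnpccError, RuntimeError):
    """A model has no information to estimate its parameter (e.g. all
    matched pairs concordant on every covariate)."""


class SeparationError(SnpccError, RuntimeError):
    """The conditional likelihood is unbounded (complete separation)."""


class MatchingError(SnpccError, RuntimeError):
    """Not enough eligible controls to complete case-control matching."""
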