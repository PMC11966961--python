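"""Exception hierarchy.

All configuration-time problems raise :class:`ConfigurationError` (a
``ValueError``), so callers can validate scenario files with a single
``except``.  Numerical failures during integration raise
:class:`IntegrationError` carrying the solver diagnostic.
"""


class MorphogrnError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(MorphogrnError, ValueError):
    """A rate constant, threshold or concentration is out of range."""


class ConfigurationError(MorphogrnError, ValueError):
    """A model/scenario description is structurally invalid."""


class MissingInputError(MorphogrnError, KeyError):
    """A required regulator concentration or input was not supplied."""


class NoSteadyStateError(InvalidParameterError):
    """Steady state requested for a system without one (e.g. decay = 0)."""


class IntegrationError(MorphogrnError, RuntimeError):
    """The ODE solver failed to converge; message carries diagnostics."""


class InsufficientDataError(MorphogrnError, ValueError):
    """The analysis window is too short for the requested classification."""


class SizeMismatchError(MorphogrnError, ValueError):
    """Two pattern summaries cover different tissues or gene sets."""
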