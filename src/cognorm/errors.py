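"""Exception hierarchy for the cognorm pipeline.

All pipeline errors derive from :class:`CognormError` so callers (and the
CLI) can catch one base class and still distinguish configuration problems
from data problems.
"""


class CognormError(Exception):
    """Base class for all cognorm errors."""


class ConfigurationError(CognormError):
    """A config file, battery spec, or input header is malformed or incomplete."""


class ValidationError(CognormError):
    """Input data violates a contract (duplicate ids, non-numeric score, ...)."""


class DegenerateNormativeError(CognormError):
    """The control group cannot support a normative model for some test
    (fewer than two observations, or zero variance)."""


class NumericalError(CognormError):
    """A numerical routine failed to reach its tolerance."""
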