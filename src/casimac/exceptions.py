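"""Exception hierarchy for casimac."""


class CasimacError(Exception):
    """Base class for all casimac errors."""


class ConfigurationError(CasimacError, ValueError):
    """A transform or backend configuration violates its validity constraints."""


class InsufficientNeighborsError(CasimacError, ValueError):
    """A neighbor pool is smaller than the requested number of neighbors."""


class DegenerateDataError(CasimacError, ValueError):
    """Training data contains duplicates that make a coefficient non-finite."""


class CapabilityError(CasimacError, TypeError):
    """A backend lacks the capability required for the requested operation."""
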