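"""Exception hierarchy for petalign."""


class PetalignError(Exception):
    """Base class for all petalign errors."""


class InputError(PetalignError):
    """Unreadable, malformed or out-of-contract input."""


class ValidationError(PetalignError):
    """A domain object violates one of its invariants."""


class SegmentationError(PetalignError):
    """Petal/background separation failed (e.g. no contrast)."""


class EstimationError(PetalignError):
    """A geometric transform could not be estimated."""


class ConfigError(PetalignError):
    """Inconsistent configuration values."""
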