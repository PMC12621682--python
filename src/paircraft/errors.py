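"""Exception hierarchy shared across the toolkit."""


class PaircraftError(Exception):
    """Base class for all toolkit errors."""


class ParseError(PaircraftError):
    """Malformed structure string or file."""


class ValidationError(PaircraftError):
    """An object violates its invariants."""


class ConflictError(PaircraftError):
    """Two constraints assign incompatible states to the same cell."""


class CapacityError(PaircraftError):
    """More pseudoknot layers required than the bracket alphabet provides."""


class UnrepresentableError(PaircraftError):
    """Structure cannot be expressed in the requested format."""


class TopologyError(PaircraftError):
    """Inconsistent pairing-graph specification."""


class FeasibilityError(PaircraftError):
    """Requested length target is outside the reachable range."""


class SamplingError(PaircraftError):
    """Rejection sampling exhausted its retry budget."""


class GeometryError(PaircraftError):
    """Degenerate coordinates or unknown geometric constants."""
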