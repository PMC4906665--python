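"""Exception hierarchy shared across the package."""


class TempowebError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(TempowebError, ValueError):
    """A function argument violates its contract (e.g. non-positive divisor)."""


class InvalidDataError(TempowebError, ValueError):
    """Input data violate an invariant (negative weight, bad category, ...)."""


class ParseError(TempowebError, ValueError):
    """A tabular input file could not be parsed; carries row/column context."""


class SpeciesLookupError(TempowebError, KeyError):
    """A species id present in a matrix is missing from the trait table."""

    def __init__(self, species_id: str, context: str = ""):
        msg = f"species {species_id!r} not found in trait table"
        if context:
            msg += f" ({context})"
        super().__init__(msg)
        self.species_id = species_id


class EmptyNetworkError(TempowebError, ValueError):
    """An operation produced or received a network with no links."""


class UndefinedMetricError(TempowebError, ValueError):
    """The requested metric is not defined for this input (too few species,
    zero total weight, ...). Callers that assemble tables should convert this
    into a missing value, never into a zero."""
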