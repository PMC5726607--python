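"""Exception hierarchy shared by all massdiffnet modules."""


class MassDiffNetError(Exception):
    """Base class for all package errors."""


class ConfigurationError(MassDiffNetError):
    """Invalid combination of options or arguments."""


class ParseError(MassDiffNetError):
    """Malformed input text (peak tables, notation strings, formulas)."""


class ValidationError(MassDiffNetError):
    """Input that parsed but violates a domain invariant."""


class IntegrityError(MassDiffNetError):
    """Internal consistency failure, e.g. an edge endpoint missing from a network."""


class GenerationError(MassDiffNetError):
    """Synthetic-data generation could not satisfy its constraints."""
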