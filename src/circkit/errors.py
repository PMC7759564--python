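"""Exception hierarchy shared across the pipeline."""


class CircKitError(Exception):
    """Base class for all pipeline errors."""


class ConfigurationError(CircKitError):
    """A parameter or configuration value violates its contract."""


class ParseError(CircKitError, ValueError):
    """Malformed text input (locus identifiers, tables, records)."""


class PlacementError(CircKitError):
    """Could not place synthetic features under the stated constraints."""


class DesignError(CircKitError):
    """No primer pair satisfies the design constraints."""


class NormalizationError(CircKitError):
    """Expression normalization is undefined for the given inputs."""
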