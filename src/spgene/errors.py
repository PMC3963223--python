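"""Exception types shared across the pipeline."""


class SpgeneError(Exception):
    """Base class for all pipeline errors."""


class EdgeListFormatError(SpgeneError, ValueError):
    """An edge-list row violates the format contract (bad score range etc.)."""


class ConfigurationError(SpgeneError, ValueError):
    """A run cannot proceed with the given inputs or settings."""
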