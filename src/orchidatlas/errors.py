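"""Shared exception types."""


class OrchidAtlasError(Exception):
    """Base class for pipeline errors."""


class ConfigError(OrchidAtlasError, ValueError):
    """Invalid configuration (rates, rule sets, grid sizes...)."""


class InputError(OrchidAtlasError, ValueError):
    """Invalid data passed to an operation (degenerate extent, empty mask...)."""


class FormatError(OrchidAtlasError, ValueError):
    """Malformed file content (missing columns, bad header...)."""
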