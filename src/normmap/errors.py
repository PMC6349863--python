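"""Exception hierarchy.

The CLI maps these onto exit codes: ConfigurationError -> 2, DataError -> 1.
"""


class NormmapError(Exception):
    """Base class for all package errors."""


class ConfigurationError(NormmapError):
    """Invalid configuration or parameters (bad spec field, unknown modality, ...)."""


class DataError(NormmapError):
    """Invalid or inconsistent data (missing covariates, grid mismatch, ...)."""
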