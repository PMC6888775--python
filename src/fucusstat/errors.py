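"""Exception hierarchy."""


class FucusStatError(Exception):
    """Base class for all package errors."""


class ConfigurationError(FucusStatError):
    """Invalid configuration value (bad range, fraction outside (0,1], ...)."""


class InputError(FucusStatError):
    """Invalid input data (non-positive Secchi, exposure <= 0 under log, ...)."""


class ConvergenceError(FucusStatError):
    """An iterative fit failed to converge (e.g. complete separation)."""
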