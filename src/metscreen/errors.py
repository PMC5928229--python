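"""Exception hierarchy shared across the package."""


class MetscreenError(Exception):
    """Base class for all errors raised by metscreen."""


class ConfigError(MetscreenError):
    """Invalid configuration value or inconsistent option combination."""


class DesignInfeasibleError(MetscreenError):
    """A barcode set satisfying the requested constraints could not be built."""


class DataError(MetscreenError):
    """Malformed or internally inconsistent input data."""
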