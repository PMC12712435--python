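"""Exception types shared across the package."""


class SpectroMicrobeError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(SpectroMicrobeError):
    """An invalid configuration field. The message names the field."""


class GridError(SpectroMicrobeError):
    """Wavelength-grid problem (extrapolation, unresolvable band, empty result)."""


class DataError(SpectroMicrobeError):
    """Invalid or degenerate data (all-zero rows, missing biomarkers, ...)."""
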