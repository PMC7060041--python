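"""Exception types shared across the package."""


class ParameterError(ValueError):
    """A numeric argument is non-finite or outside its allowed range."""


class ConfigurationError(ValueError):
    """An acquisition / pipeline configuration is internally inconsistent."""


class CalibrationError(RuntimeError):
    """PSF calibration could not find any usable bead."""


class FitError(RuntimeError):
    """A least-squares fit failed to converge or is degenerate."""


class BoutonExcluded(ValueError):
    """A bouton does not meet the minimum-events inclusion criterion."""


class SchemaError(ValueError):
    """A table or report is missing mandatory columns/keys."""
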