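"""Exception hierarchy shared across the toolkit."""


class FlickermapError(Exception):
    """Base class for all toolkit errors."""


class ParameterError(FlickermapError, ValueError):
    """A parameter is out of its documented domain."""


class FormatError(FlickermapError, ValueError):
    """An input file or array has the wrong shape, depth or layout."""


class DegenerateInputError(FlickermapError, ValueError):
    """Input is structurally valid but carries no usable signal
    (e.g. every pixel invalid, empty mask, no usable tracks)."""


class ConfigError(FlickermapError, ValueError):
    """Run configuration failed validation (unknown key, bad value)."""


class GeneratorError(FlickermapError, ValueError):
    """A synthetic-data request is inconsistent (event out of bounds,
    force outside the calibration range, ...)."""
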