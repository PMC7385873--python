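"""Exception hierarchy for the centration pipeline."""


class ICLCentrationError(Exception):
    """Base class for all package errors."""


class ConfigurationError(ICLCentrationError):
    """Invalid cohort/render/run parameters; message names the offending field."""


class RenderError(ICLCentrationError):
    """Geometry cannot be rendered (e.g. limbus ellipse exceeds the frame)."""


class FitError(ICLCentrationError):
    """Ellipse fit impossible: too few points or a degenerate configuration."""


class DetectionError(ICLCentrationError):
    """A structure (limbus, pupil, central hole) could not be located."""


class InputError(ICLCentrationError):
    """Invalid value passed to an analysis operation."""


class SchemaError(ICLCentrationError):
    """Malformed tabular input; message names the row/column."""
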