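"""Exception types shared across the pipeline."""


class CortexLVError(Exception):
    """Base class for pipeline errors."""


class ConfigError(CortexLVError, ValueError):
    """Invalid configuration or parameter value."""


class SchemaError(CortexLVError, ValueError):
    """Inputs that do not agree on subjects, masks or column layout."""


class TableParseError(CortexLVError, ValueError):
    """Malformed delimited-text input (missing cells, bad headers)."""


class FitError(CortexLVError, RuntimeError):
    """A model fit that cannot proceed (rank deficiency, degeneracy)."""
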