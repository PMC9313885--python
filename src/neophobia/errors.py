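"""Exception types shared across the pipeline stages."""


class ConfigurationError(ValueError):
    """A parameter or geometry setting is inconsistent or out of range."""


class GeometryError(ValueError):
    """A trajectory is incompatible with the arena geometry."""


class TrackingError(RuntimeError):
    """The tracker could not produce a usable trajectory."""


class SchemaError(ValueError):
    """A table is missing required columns or has malformed rows."""


class UndefinedPreferenceError(ValueError):
    """A preference index is undefined (zero total time or approaches)."""
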