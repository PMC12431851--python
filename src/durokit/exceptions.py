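"""Shared exception types."""


class DurokitError(Exception):
    """Base class for all package-specific errors."""


class OutOfExtentError(DurokitError, ValueError):
    """A coordinate falls outside the spatial extent of a pattern or map."""

    def __init__(self, point, extent):
        self.point = tuple(point)
        self.extent = tuple(extent)
        super().__init__(
            f"point {self.point} µm lies outside extent "
            f"[0, {self.extent[0]}] × [0, {self.extent[1]}] µm"
        )


class UnsupportedKindError(DurokitError, ValueError):
    """Operation not defined for this pattern kind."""


class SchemaError(DurokitError, ValueError):
    """A file or table violates the documented schema; message carries location."""
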