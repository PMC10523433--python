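"""Exception hierarchy shared across the package.

All failures raised by ligswitch derive from :class:`LigswitchError`, so
callers (including the CLI) can catch one type and report a structured
message with a nonzero exit status.
"""


class LigswitchError(Exception):
    """Base class for all ligswitch errors."""


class TrajectoryParseError(LigswitchError):
    """A trajectory file is malformed (inconsistent models, bad XYZ block...)."""


class EmptyInputError(LigswitchError):
    """A file or series contained no usable records."""


class SelectionError(LigswitchError):
    """A named selection could not be resolved to atom indices."""


class GeometryError(LigswitchError):
    """Degenerate geometry (collinear torsion triple, coincident atoms...)."""


class ConfigError(LigswitchError):
    """Invalid configuration or parameter value."""


class FormatError(LigswitchError):
    """Output cannot be represented in the requested file format."""
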