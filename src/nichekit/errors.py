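"""Exception hierarchy shared across the package."""


class NichekitError(Exception):
    """Base class for all package errors."""


class InputError(NichekitError):
    """Invalid user input: bad parameters, malformed tables, missing data."""


class FormatError(InputError):
    """A file could not be parsed in any supported dialect."""


class UnsupportedInputError(InputError):
    """The file parsed but uses a feature outside scope (e.g. multi-band)."""


class GeometryError(InputError):
    """Degenerate geometry (collinear hull input, mismatched grids...)."""
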