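"""Exception hierarchy.

All pentagate errors derive from :class:`PentagateError` so callers can catch
the package's failures with a single except clause.
"""


class PentagateError(Exception):
    """Base class for all pentagate errors."""


class FormatError(PentagateError):
    """A coordinate or trajectory file could not be parsed."""


class AssemblyError(PentagateError):
    """The model is not a pentamer (protein chain count != 5)."""


class SelectionError(PentagateError):
    """A residue/atom selection resolved to nothing or to invalid atoms."""


class AsymmetryError(SelectionError):
    """A selection that must resolve identically on all five chains did not."""


class PairingError(PentagateError):
    """Two atom sets that must correspond one-to-one do not."""


class GeometryError(PentagateError):
    """Degenerate geometry: undetermined axis, coincident azimuths, etc."""


class InsufficientDataError(PentagateError):
    """Too few observations for the requested statistical operation."""


class ConfigError(PentagateError):
    """Invalid analysis configuration (unknown key, bad value)."""
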