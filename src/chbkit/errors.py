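"""Exception hierarchy for chbkit."""


class ChbkitError(Exception):
    """Base class for all chbkit errors."""


class FormatError(ChbkitError):
    """A structure file could not be parsed in the requested format."""


class EmptyStructureError(ChbkitError):
    """A structure file contained no protein atoms."""


class SerializationError(ChbkitError):
    """A structure cannot be written in the fixed-column PDB format."""


class UnknownElementError(ChbkitError, KeyError):
    """An element is missing from the van der Waals radii table."""


class DegenerateGeometryError(ChbkitError, ValueError):
    """Coincident points make a distance/angle undefined."""


class UnpairableError(ChbkitError):
    """Two structures share no sequence-database accession."""


class ToolInvocationError(ChbkitError):
    """A configured external executable could not be run."""


class InfeasibleSpecError(ChbkitError, ValueError):
    """A toy-geometry spec forces an atom clash or an ambiguous fixture."""
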