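"""Exception hierarchy shared across the pipeline."""


class GatesiteError(Exception):
    """Base class for all package errors."""


class TopologyError(GatesiteError):
    """Ensemble frames disagree on atom count or ordering."""


class SelectionError(GatesiteError):
    """A ligand/protein selection matched nothing (or everything it must not)."""


class ConfigurationError(GatesiteError):
    """Incompatible or invalid analysis parameters."""


class MappingError(GatesiteError):
    """A residue number could not be mapped to an alignment column."""


class FormatError(GatesiteError):
    """Malformed input file (ragged alignment, duplicate identifiers, ...)."""


class GeometryError(GatesiteError):
    """Synthetic-scaffold geometry is impossible for the requested size."""
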