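"""Exception hierarchy shared across the package."""


class MolFinderError(Exception):
    """Base class for all package-specific errors."""


class ParseError(MolFinderError):
    """A string could not be parsed into a valid molecule."""


class KindMismatch(MolFinderError):
    """Two fingerprints of different kinds were compared."""


class NoAdmissibleCut(MolFinderError):
    """A SMILES string admits no ring-safe truncation point."""


class TooSmall(MolFinderError):
    """A molecule is too small for the requested edit."""


class DomainError(MolFinderError):
    """A numeric argument lies outside its permitted range."""


class MissingReference(MolFinderError):
    """A similarity objective was requested without a reference molecule."""


class InsufficientSeeds(MolFinderError):
    """Fewer unique valid seed molecules than the requested bank size."""


class ConfigError(MolFinderError):
    """Inconsistent run configuration."""


class NotEnoughRecords(MolFinderError):
    """Fewer unique records than the requested top-k size."""


class TooFew(MolFinderError):
    """Too few molecules for a pairwise statistic."""


class GenerationStall(MolFinderError):
    """The seed generator could not reach the requested number of unique molecules."""


class EmptyInput(MolFinderError):
    """An input file contained no usable molecule lines."""
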