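"""Exception hierarchy."""


class MutstabError(Exception):
    """Base class for package errors."""


class PdbParseError(MutstabError):
    """Input is not readable PDB-format text."""


class EmptyStructureError(MutstabError):
    """No standard protein residues were found."""


class MutationFormatError(MutstabError):
    """Mutation string does not match <wt><number>[icode]<mut>."""


class ResidueNotFoundError(MutstabError):
    """The mutation site does not exist in the structure."""


class WildtypeMismatchError(MutstabError):
    """Residue at the mutation site differs from the stated wildtype."""


class IncompleteResidueError(MutstabError):
    """Backbone atoms required for modelling are missing."""


class ConfigError(MutstabError):
    """Inconsistent environment scheme or configuration."""


class EsstFormatError(MutstabError):
    """Malformed substitution-table file."""


class AnnotationError(MutstabError):
    """Alignment column maps to a residue absent from the structure."""


class MetricsError(MutstabError):
    """Benchmark metrics are undefined for the given records."""
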