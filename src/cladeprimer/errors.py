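"""Exception hierarchy for the toolkit.

Every distinct input defect named in the I/O and primer contracts gets its
own class so callers (and the CLI) can map failures to exit codes without
string matching.
"""


class CladePrimerError(Exception):
    """Base class for all toolkit errors."""


class MissingFileError(CladePrimerError):
    """Input path does not exist."""


class EmptyFileError(CladePrimerError):
    """Input file contains no records."""


class DuplicateIdError(CladePrimerError):
    """Two records in one file share an id."""


class IllegalCharacterError(CladePrimerError):
    """A sequence contains a character outside the permitted alphabet."""


class AlignmentShapeError(CladePrimerError):
    """Rows of an aligned FASTA differ in length."""


class TaxonTableError(CladePrimerError):
    """Malformed taxon table (missing column, unknown role, ...)."""


class PrimerSpecError(CladePrimerError):
    """Malformed primer markup ('+' not followed by a base, bad code, ...)."""


class DegeneracyCapError(CladePrimerError):
    """A degenerate expansion would exceed the configured cap."""


class IncomparablePrimersError(CladePrimerError):
    """No anchored overlap of at least 8 compatible bases exists."""


class TemplateTooShortError(CladePrimerError):
    """Template is shorter than the primer scanned against it."""


class GappedTemplateError(CladePrimerError):
    """A gap character appeared in an unaligned template FASTA."""


class EmptyPanelError(CladePrimerError):
    """An operation that needs at least one template received none."""


class ZeroUsableSitesError(CladePrimerError):
    """A sequence pair shares no gap/ambiguity-free columns."""


class UnalignableQueryError(CladePrimerError):
    """No placement offset reaches the minimum identity to the references."""


class FixtureConfigError(CladePrimerError):
    """A synthetic-panel configuration is internally inconsistent."""
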