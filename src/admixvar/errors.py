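"""Exception hierarchy for admixvar.

Each malformed-input condition the readers and estimators can hit gets its
own class so callers can catch precisely.
"""


class AdmixvarError(Exception):
    """Base class for all admixvar errors."""


class PanelFormatError(AdmixvarError):
    """Local-ancestry panel file has a malformed header or row structure."""


class InvalidDosageError(AdmixvarError):
    """A local-ancestry dosage is outside {0, 1, 2}."""

    def __init__(self, message: str, row: int | None = None, column: str | None = None):
        super().__init__(message)
        self.row = row
        self.column = column


class LociOrderError(AdmixvarError):
    """Loci are not strictly sorted by (chromosome, position)."""


class DuplicateIndividualError(AdmixvarError):
    """Individual identifiers are not unique."""


class AlignmentError(AdmixvarError):
    """Panel and phenotype table share no individuals."""


class SchemaError(AdmixvarError):
    """Phenotype table is missing a declared column or holds the wrong type."""


class RankDeficiencyError(AdmixvarError):
    """Design matrix is rank deficient (collinear covariates)."""


class DegenerateLocusError(AdmixvarError):
    """A locus is constant (or collinear with covariates) where variation is required."""


class SimilarityError(AdmixvarError):
    """Similarity matrix construction failed (empty subset, all loci excluded, asymmetry)."""


class NonIdentifiableError(AdmixvarError):
    """REML variance components are not identifiable (projected A ~ identity)."""


class SimulationError(AdmixvarError):
    """Invalid simulation configuration."""
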