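"""Core domain types: local-ancestry panels and phenotype tables.

A :class:`LocalAncestryPanel` holds, for M individuals at N autosomal loci,
the number of chromosomes (0, 1, or 2) inherited from the reference ancestral
population (African ancestry, in the African-American setting this package
targets). The loci carry a genome map (chromosome, base-pair position,
optional genetic position in Morgans) and are strictly sorted along the
genome. No missing dosages are permitted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    AlignmentError,
    DuplicateIndividualError,
    InvalidDosageError,
    LociOrderError,
    SchemaError,
)

logger = logging.getLogger(__name__)


def chromosome_sort_key(label: str) -> tuple[int, float | str]:
    """Natural sort key for chromosome labels: 1..22 numerically, others after."""
    s = str(label)
    if s.lower().startswith("chr"):
        s = s[3:]
    if s.isdigit():
        return (0, int(s))
    return (1, s)


@dataclass(frozen=True)
class Locus:
    """One mapped locus: chromosome label, 1-based bp position, identifier,
    optional genetic position in Morgans."""

    chrom: str
    position_bp: int
    locus_id: str
    genetic_pos: float | None = None


@dataclass
class LocalAncestryPanel:
    """M individuals x N loci of integer local-ancestry dosages.

    ``dosages`` is an (N, M) integer array; entry (i, j) is the count of
    reference-ancestry chromosomes carried by individual j at locus i.
    """

    individual_ids: list[str]
    loci: list[Locus]
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.individual_ids = [str(i) for i in self.individual_ids]
        self.dosages = np.ascontiguousarray(self.dosages)
        self.validate()

    # -- invariants ---------------------------------------------------------

    def validate(self) -> None:
        M, N = len(self.individual_ids), len(self.loci)
        if M < 2:
            raise ValueError(f"panel needs at least 2 individuals, got {M}")
        if N < 1:
            raise ValueError("panel needs at least 1 locus")
        if len(set(self.individual_ids)) != M:
            raise DuplicateIndividualError("individual ids are not unique")
        if self.dosages.shape != (N, M):
            raise ValueError(
                f"dosage matrix shape {self.dosages.shape} != (n_loci={N}, n_individuals={M})"
            )
        if not np.issubdtype(self.dosages.dtype, np.integer):
            if not np.array_equal(self.dosages, np.round(self.dosages)):
                raise InvalidDosageError("dosages must be integers")
            self.dosages = self.dosages.astype(np.int8)
        bad = (self.dosages < 0) | (self.dosages > 2)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise InvalidDosageError(
                f"dosage {self.dosages[i, j]} at locus {self.loci[i].locus_id} / "
                f"individual {self.individual_ids[j]} is not in {{0,1,2}}",
                row=int(i),
                column=self.individual_ids[j],
            )
        keys = [(chromosome_sort_key(l.chrom), l.position_bp) for l in self.loci]
        if any(keys[i] >= keys[i + 1] for i in range(N - 1)):
            raise LociOrderError("loci are not strictly sorted by (chromosome, position)")
        if any(l.position_bp < 1 for l in self.loci):
            raise ValueError("positions are 1-based and must be >= 1")

    # -- shape accessors ----------------------------------------------------

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def chromosomes(self) -> list[str]:
        out: list[str] = []
        for l in self.loci:
            if not out or out[-1] != l.chrom:
                out.append(l.chrom)
        return out

    def chromosome_indices(self, chrom: str) -> np.ndarray:
        """Row indices of the loci on one chromosome (contiguous by sorting)."""
        idx = np.array([i for i, l in enumerate(self.loci) if l.chrom == str(chrom)])
        if idx.size == 0:
            raise KeyError(f"no loci on chromosome {chrom!r}")
        return idx

    def locus_index(self, locus_id: str) -> int:
        for i, l in enumerate(self.loci):
            if l.locus_id == locus_id:
                return i
        raise KeyError(f"locus {locus_id!r} not in panel")

    def subset_individuals(self, indices: np.ndarray | list[int]) -> "LocalAncestryPanel":
        idx = np.asarray(indices, dtype=int)
        return LocalAncestryPanel(
            individual_ids=[self.individual_ids[j] for j in idx],
            loci=self.loci,
            dosages=self.dosages[:, idx],
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LocalAncestryPanel):
            return NotImplemented
        return (
            self.individual_ids == other.individual_ids
            and len(self.loci) == len(other.loci)
            and all(
                a.chrom == b.chrom
                and a.position_bp == b.position_bp
                and a.locus_id == b.locus_id
                and (
                    (a.genetic_pos is None and b.genetic_pos is None)
                    or (
                        a.genetic_pos is not None
                        and b.genetic_pos is not None
                        and abs(a.genetic_pos - b.genetic_pos) < 5e-8
                    )
                )
                for a, b in zip(self.loci, other.loci)
            )
            and np.array_equal(self.dosages, other.dosages)
        )


@dataclass
class PhenotypeTable:
    """Phenotype plus covariates for a set of individuals.

    ``data`` is indexed by individual id; ``phenotype`` names the outcome
    column, ``continuous``/``discrete`` name the covariate columns. Binary
    outcomes (``binary=True``) must be coded exactly 0/1.
    """

    data: pd.DataFrame
    phenotype: str
    continuous: list[str] = field(default_factory=list)
    discrete: list[str] = field(default_factory=list)
    binary: bool = False

    def __post_init__(self) -> None:
        for col in [self.phenotype, *self.continuous, *self.discrete]:
            if col not in self.data.columns:
                raise SchemaError(f"declared column {col!r} missing from table")
        y = self.data[self.phenotype]
        if y.isna().any():
            raise SchemaError("phenotype contains missing values")
        for col in [self.phenotype, *self.continuous]:
            if not np.issubdtype(pd.to_numeric(self.data[col], errors="coerce").dtype, np.number):
                raise SchemaError(f"continuous column {col!r} is not numeric")
            if pd.to_numeric(self.data[col], errors="coerce").isna().any():
                raise SchemaError(f"non-numeric value in continuous column {col!r}")
        if self.binary:
            vals = set(np.unique(y.to_numpy()))
            if vals != {0, 1} and vals != {0.0, 1.0}:
                raise SchemaError(f"binary trait must contain exactly 0 and 1, found {vals}")
        if self.data.index.has_duplicates:
            raise DuplicateIndividualError("phenotype table ids are not unique")

    @property
    def individual_ids(self) -> list[str]:
        return [str(i) for i in self.data.index]

    def y(self) -> np.ndarray:
        return self.data[self.phenotype].to_numpy(dtype=float)

    def subset(self, ids: list[str]) -> "PhenotypeTable":
        return PhenotypeTable(
            data=self.data.loc[ids],
            phenotype=self.phenotype,
            continuous=list(self.continuous),
            discrete=list(self.discrete),
            binary=self.binary,
        )


def align(panel: LocalAncestryPanel, table: PhenotypeTable) -> tuple[LocalAncestryPanel, PhenotypeTable]:
    """Intersect a panel and a phenotype table by individual id.

    Panel order is preserved; individuals present in only one input are
    dropped (and logged). Raises :class:`AlignmentError` if the intersection
    is empty or has fewer than two individuals.
    """
    table_ids = set(table.individual_ids)
    keep = [j for j, iid in enumerate(panel.individual_ids) if iid in table_ids]
    if len(keep) < 2:
        raise AlignmentError(
            f"panel and phenotype table share {len(keep)} individuals; need at least 2"
        )
    n_drop_panel = panel.n_individuals - len(keep)
    n_drop_table = len(table_ids) - len(keep)
    if n_drop_panel or n_drop_table:
        logger.info(
            "alignment dropped %d panel and %d phenotype individuals", n_drop_panel, n_drop_table
        )
    sub_panel = panel.subset_individuals(keep)
    sub_table = table.subset(sub_panel.individual_ids)
    return sub_panel, sub_table
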