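"""File readers and writers.

Panel dialect: tab-separated, header ``chrom  pos  id  [cM]  <ind_1> ...``,
one row per locus, dosages in {0,1,2}. Similarity matrices use the GRM-style
lower-triangle text convention (columns i, j, n_loci, value with 1-based
i >= j) plus a ``.grm.id`` companion listing family and individual id.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import (
    DuplicateIndividualError,
    InvalidDosageError,
    PanelFormatError,
    SchemaError,
    SimilarityError,
)
from .panel import LocalAncestryPanel, Locus, PhenotypeTable
from .similarity import AncestrySimilarityMatrix

logger = logging.getLogger(__name__)

_PANEL_FIXED = ("chrom", "pos", "id")


def write_panel(panel: LocalAncestryPanel, path: str | Path) -> Path:
    """Write a panel in the TSV dialect; emits the cM column when mapped."""
    path = Path(path)
    has_cm = all(l.genetic_pos is not None for l in panel.loci)
    header = list(_PANEL_FIXED) + (["cM"] if has_cm else []) + list(panel.individual_ids)
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for i, locus in enumerate(panel.loci):
            row = [locus.chrom, str(locus.position_bp), locus.locus_id]
            if has_cm:
                row.append(f"{locus.genetic_pos * 100.0:.6f}")  # stored in centimorgans
            row.extend(str(int(v)) for v in panel.dosages[i])
            fh.write("\t".join(row) + "\n")
    return path


def read_local_ancestry(path: str | Path) -> LocalAncestryPanel:
    """Read and validate a panel TSV file."""
    path = Path(path)
    with open(path) as fh:
        header_line = fh.readline()
    if not header_line.strip():
        raise PanelFormatError(f"{path}: empty file")
    header = header_line.rstrip("\n").split("\t")
    if tuple(header[:3]) != _PANEL_FIXED:
        raise PanelFormatError(
            f"{path}: header must start with {' '.join(_PANEL_FIXED)}, got {header[:3]}"
        )
    has_cm = len(header) > 3 and header[3] == "cM"
    ind_start = 4 if has_cm else 3
    individual_ids = header[ind_start:]
    if not individual_ids:
        raise PanelFormatError(f"{path}: no individual columns in header")
    if len(set(individual_ids)) != len(individual_ids):
        raise DuplicateIndividualError(f"{path}: duplicate individual ids in header")

    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns) != header:
        raise PanelFormatError(f"{path}: inconsistent columns")
    loci = []
    for _, row in df.iterrows():
        loci.append(
            Locus(
                chrom=str(row["chrom"]),
                position_bp=int(row["pos"]),
                locus_id=str(row["id"]),
                genetic_pos=float(row["cM"]) / 100.0 if has_cm else None,
            )
        )
    raw = df[individual_ids].to_numpy()
    dosages = np.empty(raw.shape, dtype=np.int8)
    for i in range(raw.shape[0]):
        for j in range(raw.shape[1]):
            val = str(raw[i, j]).strip()
            if val not in ("0", "1", "2"):
                raise InvalidDosageError(
                    f"{path}: dosage {val!r} at data row {i + 1} (locus {loci[i].locus_id}), "
                    f"column {individual_ids[j]!r} is not in {{0,1,2}}",
                    row=i,
                    column=individual_ids[j],
                )
            dosages[i, j] = int(val)
    return LocalAncestryPanel(individual_ids=individual_ids, loci=loci, dosages=dosages)


def read_phenotypes(
    path: str | Path,
    phenotype: str,
    continuous: list[str] | None = None,
    discrete: list[str] | None = None,
    binary: bool = False,
) -> PhenotypeTable:
    """Read a whitespace-delimited phenotype/covariate table.

    First column is the individual id; remaining columns are typed by the
    declared schema (phenotype / continuous / discrete).
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=r"\s+")
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path}: empty phenotype file") from None
    if df.shape[1] < 2:
        raise SchemaError(f"{path}: need an id column plus at least one data column")
    df = df.set_index(df.columns[0])
    df.index = df.index.astype(str)
    continuous = list(continuous or [])
    discrete = list(discrete or [])
    for col in [phenotype, *continuous, *discrete]:
        if col not in df.columns:
            raise SchemaError(f"{path}: declared column {col!r} not found")
    for col in [phenotype, *continuous]:
        coerced = pd.to_numeric(df[col], errors="coerce")
        if coerced.isna().any() and not df[col].isna().any():
            raise SchemaError(f"{path}: non-numeric value in continuous column {col!r}")
        df[col] = coerced
    df = df.dropna(subset=[phenotype])
    return PhenotypeTable(
        data=df, phenotype=phenotype, continuous=continuous, discrete=discrete, binary=binary
    )


def write_phenotypes(table: PhenotypeTable, path: str | Path) -> Path:
    path = Path(path)
    out = table.data.copy()
    out.insert(0, "id", out.index)
    out.to_csv(path, sep="\t", index=False, float_format="%.8g")
    return path


# ---------------------------------------------------------------------------
# GRM-style similarity files


def write_similarity(A: AncestrySimilarityMatrix, prefix: str | Path) -> tuple[Path, Path]:
    """Write lower-triangle text (``.grm.txt``) and id file (``.grm.id``)."""
    if np.abs(A.values - A.values.T).max() > 1e-10:
        raise SimilarityError("refusing to write a non-symmetric matrix")
    prefix = Path(prefix)
    grm_path = prefix.with_name(prefix.name + ".grm.txt")
    id_path = prefix.with_name(prefix.name + ".grm.id")
    M = A.n_individuals
    with open(grm_path, "w") as fh:
        for i in range(M):
            for j in range(i + 1):
                fh.write(f"{i + 1}\t{j + 1}\t{A.n_loci_used}\t{A.values[i, j]:.6f}\n")
    with open(id_path, "w") as fh:
        for iid in A.individual_ids:
            fh.write(f"{iid}\t{iid}\n")  # family id duplicated from individual id
    return grm_path, id_path


def read_similarity(prefix: str | Path, estimator: str = "unknown") -> AncestrySimilarityMatrix:
    """Read a lower-triangle GRM text file back into a symmetric matrix."""
    prefix = Path(prefix)
    grm_path = prefix.with_name(prefix.name + ".grm.txt")
    id_path = prefix.with_name(prefix.name + ".grm.id")
    ids = [line.split()[1] for line in open(id_path) if line.strip()]
    M = len(ids)
    values = np.zeros((M, M))
    n_loci = 0
    with open(grm_path) as fh:
        for line in fh:
            si, sj, sn, sv = line.split()
            i, j = int(si) - 1, int(sj) - 1
            values[i, j] = values[j, i] = float(sv)
            n_loci = int(sn)
    return AncestrySimilarityMatrix(ids, values, estimator, n_loci, "genome")
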