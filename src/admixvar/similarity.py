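"""Ancestral similarity matrices and multi-way ancestry distances.

Three estimators of pairwise ancestral similarity A_jk from local-ancestry
dosages x_ij in {0,1,2}, with p_i the mean ancestry at locus i:

``ibs``
    identity in state, averaged over loci: per locus 1, 0.5, 0 as
    |x_ij - x_ik| is 0, 1, 2.
``centered_scaled``
    the GCTA-style estimator: off-diagonal
    (1/N) sum_i (x_ij - 2 p_i)(x_ik - 2 p_i) / (2 p_i (1 - p_i)); diagonal
    1 + (1/N) sum_i (x_ij^2 - (1 + 2 p_i) x_ij + 2 p_i^2) / (2 p_i (1 - p_i)).
    Loci fixed for one ancestry (p_i in {0,1}) are excluded.
``centered``
    the GEMMA-style estimator, centering without scaling:
    (1/N) sum_i (x_ij - 2 p_i)(x_ik - 2 p_i). Scaling by 2 p_i (1 - p_i) is
    deliberately omitted: locus mean ancestries are roughly uniform, not
    exponentially distributed like allele frequencies, so the inverse
    frequency weighting has no justification here.

Subsets select the genome, one chromosome, or a single locus — the three
granularities used in genome partitioning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import SimilarityError
from .panel import LocalAncestryPanel

logger = logging.getLogger(__name__)

ESTIMATORS = ("ibs", "centered_scaled", "centered")


# ---------------------------------------------------------------------------
# ancestry summaries


def global_ancestry(panel: LocalAncestryPanel) -> np.ndarray:
    """Per-individual admixture proportion: (1/2N) sum_i x_ij, in [0, 1]."""
    return panel.dosages.mean(axis=0) / 2.0


def locus_mean_ancestry(panel: LocalAncestryPanel) -> np.ndarray:
    """Per-locus mean ancestry p_i = (1/2M) sum_j x_ij, in [0, 1]."""
    return panel.dosages.mean(axis=1) / 2.0


# ---------------------------------------------------------------------------
# similarity matrices

LocusSubset = None | str | tuple[str, str] | Sequence[int] | np.ndarray


@dataclass
class AncestrySimilarityMatrix:
    """M x M symmetric ancestral similarity, tagged by estimator and subset."""

    individual_ids: list[str]
    values: np.ndarray
    estimator: str
    n_loci_used: int
    locus_subset: str = "genome"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        M = len(self.individual_ids)
        if self.values.shape != (M, M):
            raise SimilarityError(f"matrix shape {self.values.shape} does not match {M} ids")
        if not np.isfinite(self.values).all():
            raise SimilarityError("similarity matrix has non-finite entries")
        if np.abs(self.values - self.values.T).max() > 1e-12:
            raise SimilarityError("similarity matrix is not symmetric")

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)


def resolve_subset(panel: LocalAncestryPanel, subset: LocusSubset) -> tuple[np.ndarray, str]:
    """Turn a subset descriptor into locus row indices and a label.

    Accepts None / "genome", ("chromosome", label), ("locus", locus_id), or
    an explicit index sequence.
    """
    if subset is None or (isinstance(subset, str) and subset == "genome"):
        return np.arange(panel.n_loci), "genome"
    if isinstance(subset, tuple) and len(subset) == 2 and isinstance(subset[0], str):
        kind, value = subset
        if kind in ("chromosome", "chrom"):
            return panel.chromosome_indices(value), f"chromosome:{value}"
        if kind == "locus":
            return np.array([panel.locus_index(value)]), f"locus:{value}"
        raise SimilarityError(f"unknown subset kind {kind!r}")
    idx = np.asarray(subset, dtype=int)
    if idx.size == 0:
        raise SimilarityError("empty locus subset")
    return idx, f"indices[{idx.size}]"


def similarity_ibs(panel: LocalAncestryPanel, locus_subset: LocusSubset = None) -> AncestrySimilarityMatrix:
    """Identity-in-state similarity, averaged over the subset loci."""
    idx, label = resolve_subset(panel, locus_subset)
    D = panel.dosages[idx]
    N = len(idx)
    # per-locus kernel 1 - |x_j - x_k| / 2 accumulated via one-hot indicators
    same = np.zeros((panel.n_individuals, panel.n_individuals))
    adjacent = np.zeros_like(same)
    ind = [(D == v).astype(float) for v in (0, 1, 2)]
    for v in range(3):
        same += ind[v].T @ ind[v]
    for v in range(2):
        adjacent += ind[v].T @ ind[v + 1] + ind[v + 1].T @ ind[v]
    A = (same + 0.5 * adjacent) / N
    A = 0.5 * (A + A.T)
    return AncestrySimilarityMatrix(list(panel.individual_ids), A, "ibs", N, label)


def similarity_centered(panel: LocalAncestryPanel, locus_subset: LocusSubset = None) -> AncestrySimilarityMatrix:
    """Centered (unscaled) similarity: (1/N) sum_i (x_ij - 2p_i)(x_ik - 2p_i)."""
    idx, label = resolve_subset(panel, locus_subset)
    D = panel.dosages[idx].astype(float)
    p = D.mean(axis=1) / 2.0
    C = D - 2.0 * p[:, None]
    A = C.T @ C / len(idx)
    A = 0.5 * (A + A.T)
    return AncestrySimilarityMatrix(list(panel.individual_ids), A, "centered", len(idx), label)


def similarity_gcta(panel: LocalAncestryPanel, locus_subset: LocusSubset = None) -> AncestrySimilarityMatrix:
    """Centered-and-scaled similarity with the GCTA diagonal.

    Loci with p_i in {0, 1} are excluded (the 2p(1-p) scale is zero there);
    the exclusion count is logged and reflected in ``n_loci_used``.
    """
    idx, label = resolve_subset(panel, locus_subset)
    D = panel.dosages[idx].astype(float)
    p = D.mean(axis=1) / 2.0
    keep = (p > 0.0) & (p < 1.0)
    n_excluded = int((~keep).sum())
    if n_excluded:
        logger.info("centered_scaled estimator excluded %d monomorphic-ancestry loci", n_excluded)
    if not keep.any():
        raise SimilarityError("all loci in subset are fixed for one ancestry")
    D, p = D[keep], p[keep]
    N = D.shape[0]
    w = 2.0 * p * (1.0 - p)
    C = D - 2.0 * p[:, None]
    A = (C / np.sqrt(w)[:, None]).T @ (C / np.sqrt(w)[:, None]) / N
    diag = 1.0 + ((D**2 - (1.0 + 2.0 * p[:, None]) * D + 2.0 * p[:, None] ** 2) / w[:, None]).sum(axis=0) / N
    np.fill_diagonal(A, diag)
    A = 0.5 * (A + A.T)
    return AncestrySimilarityMatrix(list(panel.individual_ids), A, "centered_scaled", N, label)


_BUILDERS = {
    "ibs": similarity_ibs,
    "centered_scaled": similarity_gcta,
    "centered": similarity_centered,
}


def similarity(panel: LocalAncestryPanel, estimator: str, locus_subset: LocusSubset = None) -> AncestrySimilarityMatrix:
    """Dispatch on estimator name ('ibs', 'centered_scaled', 'centered')."""
    try:
        builder = _BUILDERS[estimator]
    except KeyError:
        raise SimilarityError(f"unknown estimator {estimator!r}; choose from {ESTIMATORS}") from None
    return builder(panel, locus_subset)


# ---------------------------------------------------------------------------
# multi-way ancestry distances (diploid unordered pairs over k ancestries)


def _as_pair(g: str | Sequence[str]) -> tuple[str, str]:
    if isinstance(g, str):
        if len(g) != 2:
            raise ValueError(f"genotype string must have two ancestry labels, got {g!r}")
        return (g[0], g[1])
    pair = tuple(str(a) for a in g)
    if len(pair) != 2:
        raise ValueError(f"genotype must be a pair of ancestry labels, got {g!r}")
    return pair  # type: ignore[return-value]


def kosman_distance(g1: str | Sequence[str], g2: str | Sequence[str], alphabet: Sequence[str] = ("A", "B", "C")) -> float:
    """Hamming-style ancestral distance for unordered diploid ancestry pairs.

    Identity in state is 1, 0.5, or 0 as both, one, or neither label is
    shared (multiset intersection); the distance is 2*(1 - identity), giving
    0 / 1 / 2. Works for any alphabet size >= 2.
    """
    a, b = _as_pair(g1), _as_pair(g2)
    alpha = set(alphabet)
    if not (set(a) <= alpha and set(b) <= alpha):
        raise ValueError(f"genotype labels {a}, {b} outside alphabet {sorted(alpha)}")
    shared = sum(min(a.count(lab), b.count(lab)) for lab in alpha)
    return float(2 - shared)


def smouse_distance(g1: str | Sequence[str], g2: str | Sequence[str], alphabet: Sequence[str] = ("A", "B", "C")) -> float:
    """Squared Euclidean ancestral distance under the triangle embedding.

    The three homozygotes sit at the vertices of an equilateral triangle and
    heterozygotes at the midpoints of the connecting sides; distances are
    squared and scaled so a homozygote and its adjacent heterozygote are 1
    apart. Yields 0, 1, 3, or 4. Requires exactly three ancestries.
    """
    if len(alphabet) != 3:
        raise ValueError("the triangle embedding is defined for exactly 3 ancestries")
    a, b = _as_pair(g1), _as_pair(g2)
    alpha = list(alphabet)
    if not (set(a) <= set(alpha) and set(b) <= set(alpha)):
        raise ValueError(f"genotype labels {a}, {b} outside alphabet {alpha}")
    # vertices of a side-2 triangle; genotype = midpoint of its allele vertices
    verts = {
        alpha[0]: np.array([0.0, 0.0]),
        alpha[1]: np.array([2.0, 0.0]),
        alpha[2]: np.array([1.0, np.sqrt(3.0)]),
    }
    pa = 0.5 * (verts[a[0]] + verts[a[1]])
    pb = 0.5 * (verts[b[0]] + verts[b[1]])
    return float(np.sum((pa - pb) ** 2))
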