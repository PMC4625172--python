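"""Fixed-effects admixture mapping.

Per locus, ordinary least squares of the (transformed) phenotype on the
covariate design plus the local-ancestry dosage; the scan reports the
ancestry coefficient, its two-sided t-test p-value, and the incremental
variance explained delta-R^2 = R^2(y ~ X + x_i) - R^2(y ~ X). Genome-wide
significance uses a partial Bonferroni correction with the effective number
of tests estimated from the autocorrelation of local ancestry.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AlignmentError, DegenerateLocusError
from .panel import LocalAncestryPanel

logger = logging.getLogger(__name__)

_DEGEN_TOL = 1e-10


@dataclass
class AdmixtureScanResult:
    """Per-locus scan output plus run metadata.

    ``table`` columns: chrom, pos, locus_id, beta, se, p_value, delta_r2,
    degenerate. Degenerate loci (constant or collinear dosage) carry NaN
    statistics and degenerate=True.
    """

    table: pd.DataFrame
    covariate_names: list[str] = field(default_factory=list)
    n_used: int = 0
    alpha: float | None = None


def _residualize(X: np.ndarray, v: np.ndarray) -> np.ndarray:
    Q, _ = np.linalg.qr(X)
    return v - Q @ (Q.T @ v)


def scan(panel: LocalAncestryPanel, y: np.ndarray, X: np.ndarray, alpha: float | None = None) -> AdmixtureScanResult:
    """OLS admixture scan of y on [X, x_i] for every panel locus."""
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n = y.shape[0]
    if X.shape[0] != n or panel.n_individuals != n:
        raise AlignmentError("panel, phenotype, and design matrix are not row-aligned")
    p = X.shape[1]
    if n <= p + 1:
        raise ValueError("need more observations than design columns + 1")
    Q, _ = np.linalg.qr(X)
    ry = y - Q @ (Q.T @ y)
    D = panel.dosages.T.astype(float)  # n x N
    RD = D - Q @ (Q.T @ D)
    sxx = np.einsum("ij,ij->j", RD, RD)
    sxy = RD.T @ ry
    rss_reduced = float(ry @ ry)
    tss = float(np.sum((y - y.mean()) ** 2))
    df = n - p - 1

    degenerate = sxx <= _DEGEN_TOL * n
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = sxy / sxx
        explained = sxy**2 / sxx
        rss_full = rss_reduced - explained
        sigma2 = rss_full / df
        se = np.sqrt(sigma2 / sxx)
        tstat = beta / se
        pvals = 2.0 * stats.t.sf(np.abs(tstat), df)
        delta_r2 = explained / tss
    for arr in (beta, se, pvals, delta_r2):
        arr[degenerate] = np.nan
    pvals = np.clip(pvals, np.nextafter(0, 1), 1.0)
    pvals[degenerate] = np.nan

    table = pd.DataFrame(
        {
            "chrom": [l.chrom for l in panel.loci],
            "pos": [l.position_bp for l in panel.loci],
            "locus_id": [l.locus_id for l in panel.loci],
            "beta": beta,
            "se": se,
            "p_value": pvals,
            "delta_r2": delta_r2,
            "degenerate": degenerate,
        }
    )
    n_deg = int(degenerate.sum())
    if n_deg:
        logger.info("scan flagged %d degenerate loci", n_deg)
    return AdmixtureScanResult(table=table, n_used=n, alpha=alpha)


def locus_variance_explained(y: np.ndarray, x: np.ndarray, X: np.ndarray) -> float:
    """delta-R^2 of adding one dosage column to the covariate design."""
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    X = np.asarray(X, dtype=float)
    ry = _residualize(X, y)
    rx = _residualize(X, x)
    sxx = float(rx @ rx)
    if sxx <= _DEGEN_TOL * y.shape[0]:
        raise DegenerateLocusError("locus dosage is constant or collinear with covariates")
    tss = float(np.sum((y - y.mean()) ** 2))
    return float((rx @ ry) ** 2 / sxx / tss)


# ---------------------------------------------------------------------------
# effective number of tests


@dataclass
class EffectiveTests:
    """AR(1)-style effective number of admixture-mapping tests.

    Per chromosome c with M_c loci and lag-1 dosage autocorrelation rho_c,
    the contribution is max(1, M_c (1 - rho_c) / (1 + rho_c)); the total is
    clamped to [n_chromosomes, N].
    """

    n_eff: float
    per_chromosome: dict[str, tuple[float, float]]  # chrom -> (rho, contribution)


def _lag1_autocorrelation(series: np.ndarray) -> float:
    """Mean cross-individual correlation of adjacent-locus dosages.

    ``series`` is (n_loci, n_individuals); constant loci are skipped.
    """
    n_loci = series.shape[0]
    cors = []
    for i in range(n_loci - 1):
        a = series[i].astype(float)
        b = series[i + 1].astype(float)
        if a.std() == 0 or b.std() == 0:
            continue
        cors.append(float(np.corrcoef(a, b)[0, 1]))
    if not cors:
        return 0.0
    return float(np.mean(cors))


def _ar1_contribution(n_loci: int, rho: float) -> float:
    rho = min(max(rho, 0.0), 1.0 - 1e-12)
    return min(float(n_loci), max(1.0, n_loci * (1.0 - rho) / (1.0 + rho)))


def effective_tests(panel: LocalAncestryPanel) -> EffectiveTests:
    """Effective number of tests from the autocorrelation of local ancestry."""
    per: dict[str, tuple[float, float]] = {}
    total = 0.0
    for chrom in panel.chromosomes:
        idx = panel.chromosome_indices(chrom)
        if idx.size < 2:
            per[chrom] = (1.0, 1.0)  # single-locus chromosome contributes exactly 1
            total += 1.0
            continue
        rho = _lag1_autocorrelation(panel.dosages[idx])
        contrib = _ar1_contribution(idx.size, rho)
        per[chrom] = (rho, contrib)
        total += contrib
    n_eff = min(float(panel.n_loci), max(float(len(per)), total))
    return EffectiveTests(n_eff=n_eff, per_chromosome=per)


def bonferroni_alpha(n_eff: float, family_alpha: float = 0.05) -> float:
    """Partial Bonferroni genome-wide significance level family_alpha / n_eff."""
    if n_eff < 1:
        raise ValueError("effective number of tests must be >= 1")
    return family_alpha / n_eff


# ---------------------------------------------------------------------------
# peak calling


@dataclass
class Peak:
    chrom: str
    locus_ids: list[str]
    best_locus: str
    best_p: float
    best_delta_r2: float


def significant_peaks(result: AdmixtureScanResult, alpha: float) -> list[Peak]:
    """Group sub-threshold loci into peaks.

    A peak is a run of loci with p <= alpha on one chromosome; a run is
    broken when more than one consecutive locus fails the threshold.
    """
    t = result.table
    peaks: list[Peak] = []
    current: list[int] = []
    gap = 0

    def flush() -> None:
        if not current:
            return
        sub = t.iloc[current]
        best = sub["p_value"].idxmin()
        peaks.append(
            Peak(
                chrom=str(t.loc[best, "chrom"]),
                locus_ids=list(sub["locus_id"]),
                best_locus=str(t.loc[best, "locus_id"]),
                best_p=float(t.loc[best, "p_value"]),
                best_delta_r2=float(t.loc[best, "delta_r2"]),
            )
        )

    prev_chrom: str | None = None
    for i in range(len(t)):
        chrom = t.iloc[i]["chrom"]
        p = t.iloc[i]["p_value"]
        hit = bool(np.isfinite(p) and p <= alpha)
        if chrom != prev_chrom:
            flush()
            current, gap = [], 0
            prev_chrom = chrom
        if hit:
            current.append(i)
            gap = 0
        elif current:
            gap += 1
            if gap > 1:
                flush()
                current, gap = [], 0
    flush()
    return peaks
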