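"""Single-component REML estimation of variance explained by local ancestry.

Model: y = X b + g + e with g ~ Normal(0, sigma2_g * A) and
e ~ Normal(0, sigma2_e * I), where A is an ancestral similarity matrix.
The restricted likelihood is maximized over (sigma2_g, sigma2_e) with
sigma2_g >= 0 and the reported quantity is the proportion of phenotypic
variance explained by local ancestry, sigma2_g / (sigma2_g + sigma2_e).

Algorithm: project y onto an orthonormal basis of the orthogonal complement
of span(X), eigendecompose the projected A once, and profile the restricted
log-likelihood down to a 1-D function of the variance ratio
lambda = sigma2_g / sigma2_e that costs O(n) per candidate. The optimum is
bracketed on a logarithmic lambda grid and refined by bounded scalar
minimization; the boundary lambda = 0 is compared explicitly, so exact-zero
estimates (a common outcome for traits with no ancestry signal) are
representable.

Before fitting, A is rescaled by M / trace(A) so that the mean modeled
genetic variance per individual is sigma2_g itself and the proportion is on
the phenotypic scale for every estimator (the unscaled centered estimator
has diagonal ~2p(1-p), far from 1; the identity-in-state and
centered-scaled estimators have diagonal ~1 and are essentially unaffected).
This is a scalar reparameterization of the same model — the per-locus
similarity entries are never re-standardized by their empirical variance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .errors import NonIdentifiableError
from .panel import LocalAncestryPanel
from .similarity import AncestrySimilarityMatrix, LocusSubset, similarity

logger = logging.getLogger(__name__)

_LOG2PI = np.log(2.0 * np.pi)


@dataclass
class VarianceComponentFit:
    """REML estimates of the ancestry and residual variance components."""

    sigma2_g: float
    sigma2_e: float
    proportion: float
    se_proportion: float
    log_reml: float
    boundary: bool
    n_used: int
    estimator: str = "unknown"
    n_fixed_effects: int = 1

    def __post_init__(self) -> None:
        if not (0.0 <= self.proportion <= 1.0):
            raise ValueError("proportion must lie in [0,1]")
        if self.boundary and self.sigma2_g != 0.0:
            raise ValueError("boundary fit must have sigma2_g = 0")
        if not np.isfinite(self.log_reml):
            raise ValueError("restricted log-likelihood is not finite")


class REMLWorkspace:
    """Projection + eigendecomposition of one (A, X) pair, reusable across
    many phenotype vectors (the bias study refits thousands of times)."""

    def __init__(
        self,
        A: np.ndarray | AncestrySimilarityMatrix,
        X: np.ndarray,
        *,
        trace_normalize: bool = True,
        estimator: str = "unknown",
        spread_tol: float = 1e-8,
    ):
        if isinstance(A, AncestrySimilarityMatrix):
            estimator = A.estimator
            A = A.values
        A = np.asarray(A, dtype=float)
        X = np.atleast_2d(np.asarray(X, dtype=float))
        n = A.shape[0]
        if X.shape[0] != n:
            raise ValueError("A and X are not row-aligned")
        p = X.shape[1]
        if n <= p + 2:
            raise ValueError("need n > number of fixed effects + 2")
        if np.linalg.matrix_rank(X) < p:
            raise ValueError("fixed-effects design is rank deficient")
        self.estimator = estimator
        self.n = n
        self.p = p
        tr = float(np.trace(A))
        if trace_normalize:
            if tr <= 0:
                raise NonIdentifiableError("similarity matrix has non-positive trace")
            A = A * (n / tr)
        Q, _ = np.linalg.qr(X, mode="complete")
        C = Q[:, p:]  # orthonormal basis of the complement of span(X)
        S = C.T @ A @ C
        S = 0.5 * (S + S.T)
        d, U = np.linalg.eigh(S)
        if d.max() - d.min() < spread_tol:
            raise NonIdentifiableError(
                "projected similarity is indistinguishable from the identity; "
                "variance components are not identifiable"
            )
        self.d = d
        self.B = C @ U  # n x m, orthonormal columns; z = B^T y
        self.m = n - p
        # lambda must keep every projected eigenvalue of V positive
        dmin = float(d.min())
        self.lambda_max = 1e6 if dmin >= 0 else min(1e6, 0.999 / (-dmin))

    # -- likelihood machinery ----------------------------------------------

    def _profile_nll(self, lam: float, z2: np.ndarray) -> float:
        """Negative profiled restricted log-likelihood at variance ratio lam."""
        w = lam * self.d + 1.0
        if w.min() <= 0:
            return np.inf
        s2e = float(np.mean(z2 / w))
        if s2e <= 0 or not np.isfinite(s2e):
            return np.inf
        return 0.5 * (self.m * (_LOG2PI + np.log(s2e) + 1.0) + float(np.sum(np.log(w))))

    def _profile_score(self, lam: float, z2: np.ndarray) -> float:
        """d(negative profiled log-likelihood)/d lambda — analytic, far better
        conditioned near the optimum than function differences."""
        w = lam * self.d + 1.0
        s2e = float(np.mean(z2 / w))
        ds2e = float(np.mean(-z2 * self.d / w**2))
        return 0.5 * (self.m * ds2e / s2e + float(np.sum(self.d / w)))

    def loglik(self, sigma2_g: float, sigma2_e: float, y: np.ndarray) -> float:
        """Restricted log-likelihood at arbitrary (sigma2_g, sigma2_e)."""
        z = self.B.T @ np.asarray(y, dtype=float)
        w = sigma2_g * self.d + sigma2_e
        if w.min() <= 0:
            return -np.inf
        return -0.5 * (self.m * _LOG2PI + float(np.sum(np.log(w))) + float(np.sum(z**2 / w)))

    def fit(self, y: np.ndarray) -> VarianceComponentFit:
        z = self.B.T @ np.asarray(y, dtype=float)
        z2 = z**2
        # bracket on a log grid, then refine; compare the boundary explicitly
        grid = np.concatenate([[0.0], np.geomspace(1e-6, self.lambda_max, 65)])
        vals = np.array([self._profile_nll(l, z2) for l in grid])
        k = int(np.argmin(vals))
        lam_best, nll_best = float(grid[k]), float(vals[k])
        lo = float(grid[max(k - 1, 0)])
        hi = float(grid[min(k + 1, len(grid) - 1)])
        if hi > lo:
            # an interior optimum is a root of the analytic profile score
            g_lo, g_hi = self._profile_score(max(lo, 1e-12), z2), self._profile_score(hi, z2)
            if g_lo < 0 < g_hi:
                lam_root = optimize.brentq(
                    lambda l: self._profile_score(l, z2), max(lo, 1e-12), hi, xtol=1e-14, rtol=1e-14
                )
                nll_root = self._profile_nll(lam_root, z2)
                if nll_root <= nll_best:
                    lam_best, nll_best = float(lam_root), float(nll_root)
            else:
                res = optimize.minimize_scalar(
                    lambda t: self._profile_nll(np.exp(t), z2),
                    bounds=(np.log(max(lo, 1e-10)), np.log(hi)),
                    method="bounded",
                    options={"xatol": 1e-12},
                )
                if res.fun < nll_best:
                    lam_best, nll_best = float(np.exp(res.x)), float(res.fun)
        nll0 = self._profile_nll(0.0, z2)
        boundary = nll0 <= nll_best + 1e-10
        if boundary:
            lam_best, nll_best = 0.0, nll0

        w = lam_best * self.d + 1.0
        s2e = float(np.mean(z2 / w))
        s2g = lam_best * s2e
        proportion = lam_best / (1.0 + lam_best)
        se = self._se_proportion(s2g, s2e)
        return VarianceComponentFit(
            sigma2_g=s2g,
            sigma2_e=s2e,
            proportion=float(proportion),
            se_proportion=se,
            log_reml=-nll_best,
            boundary=boundary,
            n_used=self.n,
            estimator=self.estimator,
            n_fixed_effects=self.p,
        )

    def _se_proportion(self, s2g: float, s2e: float) -> float:
        """Delta-method SE of sigma2_g/(sigma2_g+sigma2_e) from the expected
        information of the variance components."""
        w = s2g * self.d + s2e
        i_gg = 0.5 * float(np.sum((self.d / w) ** 2))
        i_ge = 0.5 * float(np.sum(self.d / w**2))
        i_ee = 0.5 * float(np.sum(1.0 / w**2))
        info = np.array([[i_gg, i_ge], [i_ge, i_ee]])
        try:
            cov = np.linalg.inv(info)
        except np.linalg.LinAlgError:
            return float("nan")
        total = s2g + s2e
        grad = np.array([s2e, -s2g]) / total**2
        var = float(grad @ cov @ grad)
        return float(np.sqrt(max(var, 0.0)))


def reml_fit(
    A: AncestrySimilarityMatrix | np.ndarray,
    y: np.ndarray,
    X: np.ndarray,
    *,
    trace_normalize: bool = True,
) -> VarianceComponentFit:
    """One-shot REML fit of the ancestry variance component."""
    ws = REMLWorkspace(A, X, trace_normalize=trace_normalize)
    return ws.fit(y)


def genome_partition_fit(
    panel: LocalAncestryPanel,
    y: np.ndarray,
    X: np.ndarray,
    partition: LocusSubset,
    estimator: str = "centered",
) -> VarianceComponentFit:
    """Single-component fit with A restricted to a genome partition.

    ``partition`` is None/'genome', ('chromosome', label), or
    ('locus', locus_id) — one similarity granularity at a time, fitted
    separately.
    """
    A = similarity(panel, estimator, partition)
    return reml_fit(A, y, X)


# ---------------------------------------------------------------------------
# scale conversions


def observed_to_liability(h2_obs: float, prevalence: float) -> float:
    """Convert an observed-scale 0/1-trait variance fraction to the liability
    scale: h2_obs * K(1-K) / phi(Phi^{-1}(1-K))^2, clipped to [0, 1]."""
    if not (0.0 < prevalence < 1.0):
        raise ValueError("prevalence must lie in (0,1)")
    if not (0.0 <= h2_obs <= 1.0):
        raise ValueError("h2_obs must lie in [0,1]")
    K = prevalence
    z = stats.norm.pdf(stats.norm.ppf(1.0 - K))
    h2_liab = h2_obs * K * (1.0 - K) / z**2
    if h2_liab > 1.0:
        logger.warning("liability-scale estimate %.4f exceeds 1; clipping", h2_liab)
        return 1.0
    return float(h2_liab)


def theoretical_ancestry_fraction(theta: float, fst: float) -> float:
    """Fraction of additive genetic variance due to local ancestry for a
    purely polygenic trait in a two-way admixed population:
    2 * F_ST * theta * (1 - theta)."""
    if not (0.0 <= theta <= 1.0):
        raise ValueError("theta must lie in [0,1]")
    if not (0.0 <= fst <= 1.0):
        raise ValueError("fst must lie in [0,1]")
    return 2.0 * fst * theta * (1.0 - theta)
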