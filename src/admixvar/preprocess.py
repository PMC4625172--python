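"""Phenotype transformation and covariate design.

Quantitative traits are Box-Cox transformed (to reduce non-normality) and
then winsorized at +/-3 SD (to reduce kurtosis), in that order, before any
scan or variance-component fit. Binary traits bypass transformation and are
analyzed on the observed 0/1 scale.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import RankDeficiencyError, SchemaError
from .panel import PhenotypeTable

logger = logging.getLogger(__name__)


@dataclass
class TransformResult:
    """State of the phenotype transform pipeline.

    ``lam`` is the Box-Cox exponent, ``shift`` the pre-transform offset
    applied when min(y) <= 0, and the winsorized counts record how many
    values were clipped at each tail (zero when only Box-Cox was run).
    """

    transformed: np.ndarray
    lam: float
    shift: float
    n_winsorized_low: int = 0
    n_winsorized_high: int = 0


def boxcox_transform(y: np.ndarray) -> TransformResult:
    """Box-Cox transform with lambda maximizing the profile log-likelihood.

    If min(y) <= 0, y is first shifted by -min(y) + 1e-6 * range. The
    exponent is searched over [-5, 5]; |lambda| < 1e-8 falls back to log.
    """
    y = np.asarray(y, dtype=float)
    if y.size < 10:
        raise ValueError("Box-Cox needs at least 10 observations")
    if np.ptp(y) == 0:
        raise ValueError("cannot Box-Cox transform a constant vector")
    shift = 0.0
    if y.min() <= 0:
        shift = -y.min() + 1e-6 * np.ptp(y)
    yp = y + shift

    def optimizer(fun, args=()):
        return optimize.minimize_scalar(
            fun, bounds=(-5.0, 5.0), method="bounded", options={"xatol": 1e-6}
        )

    transformed, lam = stats.boxcox(yp, optimizer=optimizer)
    if abs(lam) < 1e-8:
        transformed = np.log(yp)
        lam = 0.0
    return TransformResult(transformed=np.asarray(transformed), lam=float(lam), shift=shift)


def winsorize(y: np.ndarray, k: float = 3.0) -> np.ndarray:
    """Clip values beyond mean +/- k sample SD (single pass, no iteration).

    Mean and SD (ddof=1) come from the input; a zero-SD vector is returned
    unchanged with a warning.
    """
    y = np.asarray(y, dtype=float)
    if y.size < 2:
        raise ValueError("winsorize needs at least 2 observations")
    if k <= 0:
        raise ValueError("k must be positive")
    mu, sd = y.mean(), y.std(ddof=1)
    if sd == 0:
        warnings.warn("winsorize: zero standard deviation, returning input unchanged")
        return y.copy()
    return np.clip(y, mu - k * sd, mu + k * sd)


def transform_phenotype(y: np.ndarray, method: str = "boxcox", winsor_k: float = 3.0) -> TransformResult:
    """Full pipeline: Box-Cox (optional) then winsorize at +/- winsor_k SD."""
    y = np.asarray(y, dtype=float)
    if method == "boxcox":
        res = boxcox_transform(y)
    elif method == "none":
        res = TransformResult(transformed=y.copy(), lam=1.0, shift=0.0)
    else:
        raise ValueError(f"unknown transform {method!r}; use 'boxcox' or 'none'")
    t = res.transformed
    mu, sd = t.mean(), t.std(ddof=1)
    clipped = winsorize(t, winsor_k)
    res.n_winsorized_low = int((t < mu - winsor_k * sd).sum())
    res.n_winsorized_high = int((t > mu + winsor_k * sd).sum())
    res.transformed = clipped
    return res


def build_design_matrix(
    tbl: PhenotypeTable,
    global_ancestry: np.ndarray | None = None,
) -> tuple[np.ndarray, list[str]]:
    """Fixed-effects design: intercept + continuous columns + dummy-coded
    discrete columns (reference level dropped) + optional global ancestry.

    Raises :class:`RankDeficiencyError` if the result is not full column rank.
    """
    n = len(tbl.data)
    cols: list[np.ndarray] = [np.ones(n)]
    names = ["intercept"]
    for c in tbl.continuous:
        cols.append(tbl.data[c].to_numpy(dtype=float))
        names.append(c)
    for c in tbl.discrete:
        series = tbl.data[c]
        if series.isna().any():
            raise SchemaError(f"missing values in discrete covariate {c!r}")
        dummies = pd.get_dummies(series.astype("category"), prefix=c, drop_first=True)
        for dc in dummies.columns:
            cols.append(dummies[dc].to_numpy(dtype=float))
            names.append(str(dc))
    if global_ancestry is not None:
        ga = np.asarray(global_ancestry, dtype=float)
        if ga.shape[0] != n:
            raise ValueError("global ancestry length does not match table")
        cols.append(ga)
        names.append("global_ancestry")
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise RankDeficiencyError(f"design matrix is rank deficient (columns: {names})")
    return X, names
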