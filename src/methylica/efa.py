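"""Exploratory factor analysis of adjusted regional thickness measures.

Factor count by parallel analysis, extraction by iterated principal-axis
factoring on the correlation matrix, varimax rotation, Thurstone
regression-method factor scores, and scoring of a second sample with the
training solution.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.multivariate.factor_rotation import rotate_factors

from ._rng import stream

logger = logging.getLogger(__name__)

__all__ = ["FactorModel", "parallel_analysis", "fit_efa", "factor_scores"]


@dataclass
class FactorModel:
    loadings: np.ndarray  # regions x factors (rotated)
    n_factors: int
    communalities: np.ndarray
    score_weights: np.ndarray  # regions x factors, W = R^-1 Lambda
    variance_explained: np.ndarray  # per-factor fraction of total variance
    rotation: str
    region_names: list[str]
    train_means: np.ndarray
    train_sds: np.ndarray
    heywood: bool = False

    def loading_table(self, min_abs: float = 0.3) -> pd.DataFrame:
        """Loadings with the conventional |loading| >= 0.3 display rule."""
        frame = pd.DataFrame(
            self.loadings,
            index=self.region_names,
            columns=[f"F{j + 1}" for j in range(self.n_factors)],
        )
        return frame.where(frame.abs() >= min_abs)


def _correlation(data: np.ndarray) -> np.ndarray:
    return np.corrcoef(data, rowvar=False)


def parallel_analysis(
    data: np.ndarray | pd.DataFrame,
    n_iter: int = 1000,
    quantile: float = 0.95,
    seed: int = 0,
) -> int:
    """Number of correlation eigenvalues exceeding a permutation null.

    Each null iteration permutes every column independently; the i-th
    observed eigenvalue is compared to the chosen quantile of the i-th
    null eigenvalues, counting leading exceedances until the first failure.
    """
    if n_iter < 100:
        raise ValueError("n_iter must be >= 100")
    values = data.to_numpy(dtype=float) if isinstance(data, pd.DataFrame) else np.asarray(data, float)
    n, p = values.shape
    obs = np.sort(np.linalg.eigvalsh(_correlation(values)))[::-1]
    rng = stream(seed, "parallel-analysis")
    null = np.empty((n_iter, p))
    perm = values.copy()
    for it in range(n_iter):
        for j in range(p):
            rng.shuffle(perm[:, j])
        null[it] = np.sort(np.linalg.eigvalsh(_correlation(perm)))[::-1]
    thresholds = np.quantile(null, quantile, axis=0)
    count = 0
    for o, t in zip(obs, thresholds):
        if o > t:
            count += 1
        else:
            break
    return count


def _principal_axis(corr: np.ndarray, n_factors: int, max_iter: int = 200, tol: float = 1e-8):
    p = corr.shape[0]
    try:
        inv = np.linalg.inv(corr)
        comm = 1.0 - 1.0 / np.diag(inv)  # squared multiple correlations
    except np.linalg.LinAlgError:
        comm = np.full(p, 0.5)
    comm = np.clip(comm, 1e-6, 1.0)
    heywood = False
    loadings = np.zeros((p, n_factors))
    for _ in range(max_iter):
        reduced = corr.copy()
        np.fill_diagonal(reduced, comm)
        eigval, eigvec = np.linalg.eigh(reduced)
        order = np.argsort(eigval)[::-1][:n_factors]
        lam = eigval[order]
        lam = np.clip(lam, 0.0, None)
        loadings = eigvec[:, order] * np.sqrt(lam)
        new_comm = (loadings**2).sum(axis=1)
        if new_comm.max() > 1.0 + 1e-8:
            heywood = True
            new_comm = np.clip(new_comm, None, 1.0)
        if np.abs(new_comm - comm).max() < tol:
            comm = new_comm
            break
        comm = new_comm
    return loadings, comm, heywood


def fit_efa(data: np.ndarray | pd.DataFrame, n_factors: int, rotation: str = "varimax") -> FactorModel:
    """Iterated principal-axis factoring with varimax rotation.

    Factors are oriented so that the largest-|loading| region of each
    factor loads positively; a Heywood case (communality > 1 during
    iteration) is clipped and flagged with a warning.
    """
    if isinstance(data, pd.DataFrame):
        region_names = list(map(str, data.columns))
        values = data.to_numpy(dtype=float)
    else:
        values = np.asarray(data, dtype=float)
        region_names = [f"region{j + 1}" for j in range(values.shape[1])]
    n, p = values.shape
    if not 1 <= n_factors < p:
        raise ValueError("n_factors must be in [1, n_regions)")
    corr = _correlation(values)
    if np.linalg.eigvalsh(corr).min() <= 1e-10:
        warnings.warn("correlation matrix is singular or near-singular", stacklevel=2)

    loadings, comm, heywood = _principal_axis(corr, n_factors)
    if heywood:
        warnings.warn("Heywood case: communalities clipped at 1", stacklevel=2)

    if rotation == "varimax" and n_factors > 1:
        loadings, _ = rotate_factors(loadings, "varimax")
    elif rotation not in ("varimax", "none"):
        raise ValueError("rotation must be 'varimax' or 'none'")

    # sign convention: anchor region of each factor loads positively
    for j in range(loadings.shape[1]):
        anchor = np.argmax(np.abs(loadings[:, j]))
        if loadings[anchor, j] < 0:
            loadings[:, j] = -loadings[:, j]
    # order factors by explained variance, largest first
    ssl = (loadings**2).sum(axis=0)
    order = np.argsort(ssl)[::-1]
    loadings = loadings[:, order]
    ssl = ssl[order]

    try:
        weights = np.linalg.solve(corr, loadings)
    except np.linalg.LinAlgError:
        eps = 1e-8
        logger.warning("singular correlation matrix; ridge fallback eps=%g", eps)
        weights = np.linalg.solve(corr + eps * np.eye(p), loadings)

    return FactorModel(
        loadings=loadings,
        n_factors=n_factors,
        communalities=(loadings**2).sum(axis=1),
        score_weights=weights,
        variance_explained=ssl / p,
        rotation=rotation,
        region_names=region_names,
        train_means=values.mean(axis=0),
        train_sds=values.std(axis=0, ddof=1),
        heywood=heywood,
    )


def factor_scores(model: FactorModel, data: np.ndarray | pd.DataFrame) -> np.ndarray:
    """Thurstone regression scores using the training standardization.

    Passing the training data reproduces the training scores (mean 0); a
    new sample is standardized with the training means and sds so scores
    are comparable across cohorts.
    """
    values = data.to_numpy(dtype=float) if isinstance(data, pd.DataFrame) else np.asarray(data, float)
    if values.shape[1] != len(model.region_names):
        raise ValueError("region count does not match the fitted model")
    std = (values - model.train_means) / model.train_sds
    return std @ model.score_weights
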