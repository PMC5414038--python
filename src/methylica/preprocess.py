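"""From raw beta values to the standardized residual matrix fed into ICA.

The stages are: CpG missing-rate filtering, k-nearest-neighbour imputation,
optional surrogate-variable estimation that protects a designated covariate
(chronological age), covariate residualization and per-CpG standardization.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "BetaMatrix",
    "ResidualMatrix",
    "filter_cpgs",
    "impute_missing",
    "estimate_surrogates",
    "residualize",
]


@dataclass
class BetaMatrix:
    """Sample x CpG methylation fractions in [0, 1]; NaN marks missing."""

    values: np.ndarray
    sample_ids: list[str]
    cpg_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.cpg_ids = [str(c) for c in self.cpg_ids]
        n, p = self.values.shape
        if n != len(self.sample_ids) or p != len(self.cpg_ids):
            raise ValueError("ID lists do not match matrix shape")
        if len(set(self.sample_ids)) != n or len(set(self.cpg_ids)) != p:
            raise ValueError("sample and CpG IDs must be unique")
        observed = self.values[~np.isnan(self.values)]
        if observed.size and (observed.min() < 0 or observed.max() > 1):
            raise ValueError("non-missing beta values must lie in [0, 1]")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_cpgs(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.cpg_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "BetaMatrix":
        return cls(frame.to_numpy(dtype=float), list(frame.index), list(frame.columns))

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="sample_id", float_format="%.10g")

    @classmethod
    def read_tsv(cls, path) -> "BetaMatrix":
        return cls.from_frame(pd.read_csv(path, sep="\t", index_col=0))


@dataclass
class ResidualMatrix:
    """Covariate-adjusted, per-CpG standardized methylation matrix.

    Each column has mean 0 and (ddof=1) standard deviation 1; no missing
    values are allowed.
    """

    values: np.ndarray
    sample_ids: list[str]
    cpg_ids: list[str]
    adjusted_for: tuple[str, ...] = ()
    n_surrogates: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.isnan(self.values).any():
            raise ValueError("residual matrix must not contain missing values")
        means = self.values.mean(axis=0)
        sds = self.values.std(axis=0, ddof=1)
        if np.abs(means).max(initial=0.0) > 1e-8:
            raise ValueError("residual columns must have mean 0")
        if sds.size and np.abs(sds - 1.0).max() > 1e-8:
            raise ValueError("residual columns must have unit standard deviation")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_cpgs(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.cpg_ids)

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="sample_id", float_format="%.10g")

    @classmethod
    def read_tsv(cls, path) -> "ResidualMatrix":
        frame = pd.read_csv(path, sep="\t", index_col=0)
        return cls(frame.to_numpy(dtype=float), list(frame.index), list(frame.columns))


def filter_cpgs(betas: BetaMatrix, max_missing_rate: float = 0.05) -> BetaMatrix:
    """Drop CpGs whose missing rate is >= ``max_missing_rate``.

    Column order of the survivors is preserved.
    """
    if not 0.0 <= max_missing_rate <= 1.0:
        raise ValueError("max_missing_rate must lie in [0, 1]")
    rates = np.isnan(betas.values).mean(axis=0)
    keep = rates < max_missing_rate
    if not keep.any():
        raise ValueError("missing-rate filter removed every CpG")
    dropped = int((~keep).sum())
    if dropped:
        logger.info("filter_cpgs: removed %d/%d CpGs", dropped, keep.size)
    return BetaMatrix(
        betas.values[:, keep],
        betas.sample_ids,
        [c for c, k in zip(betas.cpg_ids, keep) if k],
    )


def impute_missing(betas: BetaMatrix, k_neighbours: int = 10) -> BetaMatrix:
    """k-nearest-neighbour imputation of missing betas.

    Neighbours are other samples, ranked by Euclidean distance over
    mutually observed CpGs (distance normalized by the number of shared
    CpGs so rows with different missingness are comparable). Observed
    entries are never altered.
    """
    if k_neighbours < 1:
        raise ValueError("k_neighbours must be >= 1")
    values = betas.values.copy()
    missing = np.isnan(values)
    if not missing.any():
        return betas
    if missing.all(axis=0).any():
        bad = [c for c, m in zip(betas.cpg_ids, missing.all(axis=0)) if m]
        raise ValueError(f"CpGs with no observed values (filter first): {bad[:5]}")

    n = values.shape[0]
    obs = ~missing
    # mean normalized squared distance over shared observed CpGs
    filled0 = np.where(missing, 0.0, values)
    shared = obs.astype(float) @ obs.T.astype(float)
    sq = (
        (filled0**2) @ obs.T.astype(float)
        - 2.0 * filled0 @ filled0.T
        + obs.astype(float) @ (filled0**2).T
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        dist = np.where(shared > 0, sq / np.maximum(shared, 1), np.inf)
    np.fill_diagonal(dist, np.inf)

    for i in range(n):
        cols = np.flatnonzero(missing[i])
        if cols.size == 0:
            continue
        order = np.argsort(dist[i], kind="stable")
        for j in cols:
            donors = [o for o in order if obs[o, j] and np.isfinite(dist[i, o])]
            if not donors:  # fall back to the column mean of observed values
                values[i, j] = values[obs[:, j], j].mean()
                continue
            use = donors[:k_neighbours]
            values[i, j] = values[use, j].mean()
    out = np.clip(values, 0.0, 1.0)
    return BetaMatrix(out, betas.sample_ids, betas.cpg_ids)


def _design_matrix(covariates: pd.DataFrame | None, n: int) -> tuple[np.ndarray, list[str]]:
    if covariates is None or covariates.shape[1] == 0:
        return np.ones((n, 1)), ["intercept"]
    mat = np.column_stack([np.ones(n), covariates.to_numpy(dtype=float)])
    return mat, ["intercept", *map(str, covariates.columns)]


def _check_full_rank(design: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # identify offending columns by greedy rank growth
        bad = []
        kept: list[int] = []
        for j in range(design.shape[1]):
            trial = design[:, kept + [j]]
            if np.linalg.matrix_rank(trial) > len(kept):
                kept.append(j)
            else:
                bad.append(names[j])
        raise ValueError(f"covariate design is rank-deficient; collinear columns: {bad}")


def estimate_surrogates(
    betas: BetaMatrix,
    protected: np.ndarray,
    known: pd.DataFrame | None = None,
    n_sv: int | str = "auto",
) -> pd.DataFrame:
    """Estimate surrogate variables while protecting one covariate.

    Two-step estimator: (1) residualize every CpG on the known covariates
    *and* the protected covariate, (2) take the leading left singular
    vectors of the residual matrix. The number of surrogates is either
    given or chosen by the Marchenko-Pastur edge rule on the standardized
    residuals. Each surrogate is exactly orthogonal to the protected
    covariate by construction of OLS residuals.
    """
    from .decompose import estimate_k_rmt  # local import avoids a cycle

    protected = np.asarray(protected, dtype=float).ravel()
    n = betas.n_samples
    if protected.size != n:
        raise ValueError("protected covariate length does not match sample count")
    values = betas.values
    if np.isnan(values).any():
        raise ValueError("impute missing values before surrogate estimation")

    known_df = known if known is not None else pd.DataFrame(index=betas.sample_ids)
    design, names = _design_matrix(known_df, n)
    design = np.column_stack([design, protected])
    names = names + ["<protected>"]
    _check_full_rank(design, names)
    rank = design.shape[1]

    if isinstance(n_sv, str):
        if n_sv != "auto":
            raise ValueError("n_sv must be an integer or 'auto'")
    elif n_sv >= n - rank:
        raise ValueError("n_sv must be < n_samples - rank(known design)")

    coef, *_ = np.linalg.lstsq(design, values, rcond=None)
    resid = values - design @ coef
    sds = resid.std(axis=0, ddof=1)
    keep = sds > 1e-12
    std = (resid[:, keep] - resid[:, keep].mean(axis=0)) / resid[:, keep].std(axis=0, ddof=1)

    if n_sv == "auto":
        n_sv = estimate_k_rmt(std)
    n_sv = int(n_sv)
    if n_sv == 0:
        return pd.DataFrame(index=betas.sample_ids)
    u, s, _ = np.linalg.svd(resid, full_matrices=False)
    svs = u[:, :n_sv] * np.sqrt(n)
    cols = {f"sv{i + 1}": svs[:, i] for i in range(n_sv)}
    return pd.DataFrame(cols, index=betas.sample_ids)


def residualize(
    betas: BetaMatrix,
    covariates: pd.DataFrame | None = None,
    adjusted_for: tuple[str, ...] | None = None,
) -> ResidualMatrix:
    """OLS-residualize every CpG on the covariates, then standardize.

    CpGs whose residuals have (numerically) zero variance are dropped with
    a warning, since standardization is undefined for them.
    """
    values = betas.values
    if np.isnan(values).any():
        raise ValueError("impute missing values before residualization")
    n = betas.n_samples
    design, names = _design_matrix(covariates, n)
    _check_full_rank(design, names)
    coef, *_ = np.linalg.lstsq(design, values, rcond=None)
    resid = values - design @ coef
    sds = resid.std(axis=0, ddof=1)
    keep = sds > 1e-10 * max(1.0, np.abs(values).max())
    if not keep.all():
        dropped = [c for c, k in zip(betas.cpg_ids, keep) if not k]
        warnings.warn(
            f"dropping {len(dropped)} zero-variance CpGs after residualization",
            stacklevel=2,
        )
        logger.warning("residualize: dropped zero-variance CpGs: %s...", dropped[:5])
        resid = resid[:, keep]
        sds = sds[keep]
    if resid.shape[1] == 0:
        raise ValueError("all CpGs were constant after residualization")
    std = (resid - resid.mean(axis=0)) / sds
    if adjusted_for is None:
        adjusted_for = tuple(names[1:])
    n_sur = sum(1 for c in (covariates.columns if covariates is not None else []) if str(c).startswith("sv"))
    return ResidualMatrix(
        std,
        betas.sample_ids,
        [c for c, k in zip(betas.cpg_ids, keep) if k],
        adjusted_for=tuple(adjusted_for),
        n_surrogates=n_sur,
    )
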