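"""Stability-clustered ICA of the residual methylation matrix.

The component count is chosen by a Marchenko-Pastur (random matrix theory)
edge rule, ICA is restarted from many random initializations, the pooled
mixing columns are clustered by complete linkage on 1 - |r|, and each final
component is the centrotype of its cluster. Components dominated by a
single sample are flagged and excluded from downstream testing.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import skew
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

from ._rng import stream
from .preprocess import ResidualMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "ICAModel",
    "ComponentPattern",
    "estimate_k_rmt",
    "run_ica_restarts",
    "centrotype_cluster",
    "dominance_filter",
]


@dataclass
class ICAModel:
    """Result of the stability-clustered decomposition X ~ A @ S."""

    loadings: np.ndarray  # k x p, unit-sd rows
    mixing: np.ndarray  # n x k
    sample_ids: list[str]
    cpg_ids: list[str]
    k: int
    n_restarts: int
    stability: np.ndarray  # per-component mean within-cluster |r|
    dominance: np.ndarray  # per-component max single-sample variance share
    retained: np.ndarray  # bool flags
    seed: int | None = None

    def component_ids(self) -> list[str]:
        return [f"IC{i + 1}" for i in range(self.k)]

    def pattern(self, component: int | str) -> "ComponentPattern":
        idx = self._index(component)
        return ComponentPattern(
            weights=self.mixing[:, idx].copy(),
            component_id=self.component_ids()[idx],
            stability=float(self.stability[idx]),
            dominance=float(self.dominance[idx]),
            sample_ids=list(self.sample_ids),
        )

    def _index(self, component: int | str) -> int:
        if isinstance(component, str):
            return self.component_ids().index(component)
        return int(component)


@dataclass
class ComponentPattern:
    """One column of the mixing matrix: a per-sample methylation pattern."""

    weights: np.ndarray
    component_id: str
    stability: float
    dominance: float
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float).ravel()
        if len(self.sample_ids) != self.weights.size:
            raise ValueError("weights length must equal sample count")


def estimate_k_rmt(X: ResidualMatrix | np.ndarray) -> int:
    """Count eigenvalues above the Marchenko-Pastur upper edge.

    With ``n`` samples and ``p`` variables (p >= n), the eigenvalues of
    X X' / p for a pure-noise standardized matrix concentrate below
    (1 + sqrt(n/p))^2; the number above that edge estimates the signal
    dimension. When p < n the roles of n and p are swapped.
    """
    values = X.values if isinstance(X, ResidualMatrix) else np.asarray(X, dtype=float)
    n, p = values.shape
    if n < 3:
        raise ValueError("need at least 3 samples")
    if p < n:
        values = values.T
        n, p = p, n
    # standardize columns defensively; a ResidualMatrix is already standard
    sd = values.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    std = (values - values.mean(axis=0)) / sd
    cov = std @ std.T / p
    eig = np.linalg.eigvalsh(cov)
    edge = (1.0 + np.sqrt(n / p)) ** 2
    return int((eig > edge).sum())


def run_ica_restarts(
    X: ResidualMatrix | np.ndarray,
    k: int,
    n_restarts: int = 30,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-6,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Run FastICA ``n_restarts`` times; return converged (A_r, S_r) pairs.

    The decomposition treats CpGs as observations so that the estimated
    sources are the (heavy-tailed) CpG loading rows S (k x p) and the
    mixing matrix A (n x k) holds per-sample weights: X = A @ S.
    Non-converged restarts are dropped with a logged count.
    """
    values = X.values if isinstance(X, ResidualMatrix) else np.asarray(X, dtype=float)
    n, p = values.shape
    if not 1 <= k <= min(n, p):
        raise ValueError("k must be in [1, min(n_samples, n_cpgs)]")
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")

    runs: list[tuple[np.ndarray, np.ndarray]] = []
    n_failed = 0
    for r in range(n_restarts):
        rng = stream(seed, "ica-restart", str(r))
        ica = FastICA(
            n_components=k,
            fun="logcosh",
            whiten="unit-variance",
            max_iter=max_iter,
            tol=tol,
            random_state=np.random.RandomState(rng.integers(0, 2**31 - 1)),
        )
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always", ConvergenceWarning)
            sources = ica.fit_transform(values.T)  # p x k
            converged = not any(issubclass(w.category, ConvergenceWarning) for w in caught)
        if not converged:
            n_failed += 1
            continue
        S_r = sources.T  # k x p
        A_r = ica.mixing_  # n x k
        runs.append((A_r, S_r))
    if n_failed:
        logger.warning("run_ica_restarts: %d/%d restarts did not converge", n_failed, n_restarts)
    if not runs:
        raise RuntimeError("no ICA restart converged; consider lowering k")
    return runs


def _abs_corr(columns: np.ndarray) -> np.ndarray:
    """Absolute Pearson correlation between the columns of a matrix."""
    std = (columns - columns.mean(axis=0)) / columns.std(axis=0, ddof=0)
    r = np.abs(std.T @ std / columns.shape[0])
    return np.clip(r, 0.0, 1.0)


def _orient(S: np.ndarray, A: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic sign convention: positive loading-row skewness."""
    S = S.copy()
    A = A.copy()
    for j in range(S.shape[0]):
        sk = skew(S[j])
        if abs(sk) < 1e-12:
            flip = S[j][np.argmax(np.abs(S[j]))] < 0
        else:
            flip = sk < 0
        if flip:
            S[j] = -S[j]
            A[:, j] = -A[:, j]
    return S, A


def centrotype_cluster(
    runs: list[tuple[np.ndarray, np.ndarray]],
    k: int,
    X: ResidualMatrix | np.ndarray,
    sample_ids: list[str] | None = None,
    cpg_ids: list[str] | None = None,
    n_restarts: int | None = None,
    seed: int | None = None,
) -> ICAModel:
    """Cluster pooled mixing columns and keep one centrotype per cluster.

    Distance is 1 - |r| between mixing columns, agglomerated with complete
    linkage and cut at ``k`` clusters. The centrotype is the member with
    the largest summed similarity to its cluster; stability is the mean
    pairwise |r| within the cluster. Loadings are recomputed from X by
    least squares and rescaled so every loadings row has unit sd.
    """
    if not runs:
        raise ValueError("need at least one converged run")
    values = X.values if isinstance(X, ResidualMatrix) else np.asarray(X, dtype=float)
    pooled = np.column_stack([A_r for A_r, _ in runs])  # n x (k*R)
    m = pooled.shape[1]
    if k > m:
        raise ValueError(f"k={k} exceeds the {m} pooled mixing columns")

    sim = _abs_corr(pooled)
    dist = 1.0 - sim
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2.0
    if m > 1:
        Z = linkage(squareform(dist, checks=False), method="complete")
        labels = fcluster(Z, t=k, criterion="maxclust")
    else:
        labels = np.ones(1, dtype=int)

    centrotypes = []
    stability = []
    for c in range(1, int(labels.max()) + 1):
        members = np.flatnonzero(labels == c)
        sub = sim[np.ix_(members, members)]
        scores = sub.sum(axis=1)
        centro = members[int(np.argmax(scores))]
        centrotypes.append(centro)
        if members.size > 1:
            off = sub[np.triu_indices(members.size, 1)]
            stability.append(float(off.mean()))
        else:
            stability.append(1.0)

    A = pooled[:, centrotypes]  # n x k
    # Align the mixing matrix with the rank-k signal subspace of X so that
    # A @ S below equals the leading-k singular reconstruction exactly.
    # ICA whitening row-centres X, so raw centrotypes sit a hair off that
    # subspace; the projection is numerically tiny but makes the
    # reconstruction identity hold to machine precision.
    gram = values @ values.T
    eigval, eigvec = np.linalg.eigh(gram)
    U_k = eigvec[:, ::-1][:, :k]
    A_proj = U_k @ (U_k.T @ A)
    if np.linalg.matrix_rank(A_proj) < k:
        raise ValueError("centrotype mixing columns are rank-deficient in the signal subspace")
    A = A_proj
    # recompute loadings from the data for the final mixing matrix
    S, *_ = np.linalg.lstsq(A, values, rcond=None)
    # scale convention: unit-sd loading rows
    row_sd = S.std(axis=1, ddof=0)
    if np.any(row_sd == 0):
        raise ValueError("degenerate (constant) loadings row after clustering")
    S = S / row_sd[:, None]
    A = A * row_sd[None, :]
    S, A = _orient(S, A)

    dominance = _dominance(A)
    n, p = values.shape
    sample_ids = sample_ids or (X.sample_ids if isinstance(X, ResidualMatrix) else [f"s{i}" for i in range(n)])
    cpg_ids = cpg_ids or (X.cpg_ids if isinstance(X, ResidualMatrix) else [f"cg{j}" for j in range(p)])
    return ICAModel(
        loadings=S,
        mixing=A,
        sample_ids=list(sample_ids),
        cpg_ids=list(cpg_ids),
        k=k,
        n_restarts=n_restarts if n_restarts is not None else len(runs),
        stability=np.asarray(stability),
        dominance=dominance,
        retained=np.ones(k, dtype=bool),
        seed=seed,
    )


def _dominance(A: np.ndarray) -> np.ndarray:
    ss = (A**2).sum(axis=0)
    if np.any(ss == 0):
        raise ValueError("zero-variance mixing column")
    return (A**2).max(axis=0) / ss


def dominance_filter(model: ICAModel, threshold: float = 0.10) -> ICAModel:
    """Flag components whose largest single-sample share exceeds ``threshold``.

    A and S are not mutated; only the ``retained`` flags change.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must lie in (0, 1]")
    dominance = _dominance(model.mixing)
    retained = dominance <= threshold
    n_flagged = int((~retained).sum())
    if n_flagged:
        logger.info(
            "dominance_filter: %d/%d components dominated by single samples (>%.2f)",
            n_flagged,
            model.k,
            threshold,
        )
    return replace(model, dominance=dominance, retained=retained)


def decompose(
    X: ResidualMatrix,
    k: int | str = "auto",
    n_restarts: int = 30,
    dominance_threshold: float = 0.10,
    seed: int = 0,
) -> ICAModel:
    """Convenience driver: RMT order selection, restarts, clustering, filter."""
    if k == "auto":
        k = estimate_k_rmt(X)
    k = int(k)
    if k < 1:
        raise ValueError("estimated component count is 0; nothing to decompose")
    runs = run_ica_restarts(X, k=k, n_restarts=n_restarts, seed=seed)
    model = centrotype_cluster(runs, k=k, X=X, n_restarts=n_restarts, seed=seed)
    return dominance_filter(model, threshold=dominance_threshold)
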