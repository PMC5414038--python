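"""Component-phenotype association testing.

Pearson correlations with explicit Bonferroni families, asymmetric
partialling-out of covariates (two age variables), and a nested F-test
against a polynomial age baseline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AssociationResult",
    "correlate",
    "partial_out",
    "adjusted_correlation",
    "nested_poly_ftest",
]


@dataclass
class AssociationResult:
    r: float
    p_nominal: float
    p_corrected: float
    n_tests: int
    n_obs: int
    sidedness: str  # "two-sided", "less" or "greater"
    adjusted_for: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not -1.0 <= self.r <= 1.0:
            raise ValueError("correlation outside [-1, 1]")
        if self.n_obs < 3:
            raise ValueError("need at least 3 observations")
        expected = min(1.0, self.p_nominal * self.n_tests)
        if abs(self.p_corrected - expected) > 1e-12:
            raise ValueError("p_corrected must equal min(1, p_nominal * n_tests)")


def bonferroni(p_nominal: float, n_tests: int) -> float:
    """min(1, p * m) family-wise correction."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return min(1.0, float(p_nominal) * int(n_tests))


def _clean_pair(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("paired vectors must have equal length")
    ok = ~(np.isnan(x) | np.isnan(y))
    return x[ok], y[ok]


def correlate(
    x,
    y,
    sidedness: str = "two-sided",
    n_tests: int = 1,
    adjusted_for: tuple[str, ...] = (),
) -> AssociationResult:
    """Pearson correlation with a t-test p-value and Bonferroni correction."""
    x, y = _clean_pair(x, y)
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 paired non-missing observations")
    if x.std(ddof=0) == 0 or y.std(ddof=0) == 0:
        raise ValueError("constant input")
    if sidedness not in ("two-sided", "less", "greater"):
        raise ValueError("sidedness must be 'two-sided', 'less' or 'greater'")
    res = stats.pearsonr(x, y, alternative=sidedness)
    r = float(res.statistic)
    p = float(res.pvalue)
    return AssociationResult(
        r=r,
        p_nominal=p,
        p_corrected=bonferroni(p, n_tests),
        n_tests=int(n_tests),
        n_obs=n,
        sidedness=sidedness,
        adjusted_for=adjusted_for,
    )


def partial_out(x, z: pd.DataFrame | np.ndarray | None) -> np.ndarray:
    """OLS residual of x on an intercept plus the columns of z."""
    x = np.asarray(x, dtype=float).ravel()
    n = x.size
    if z is None:
        return x - x.mean()
    zmat = z.to_numpy(dtype=float) if isinstance(z, pd.DataFrame) else np.asarray(z, dtype=float)
    if zmat.ndim == 1:
        zmat = zmat[:, None]
    if zmat.shape[1] == 0:
        return x - x.mean()
    if zmat.shape[0] != n:
        raise ValueError("covariate rows must match vector length")
    design = np.column_stack([np.ones(n), zmat])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("rank-deficient covariate design")
    coef, *_ = np.linalg.lstsq(design, x, rcond=None)
    return x - design @ coef


def adjusted_correlation(
    x,
    y,
    z_x=None,
    z_y=None,
    sidedness: str = "two-sided",
    n_tests: int = 1,
    adjusted_for: tuple[str, ...] = (),
) -> AssociationResult:
    """Correlate after partialling possibly different covariates out of each side.

    Supports the asymmetric adjustment used for the two age variables
    (age at profiling removed from the pattern, age at assessment from the
    phenotype) as well as symmetric cell-count adjustment.
    """
    rx = partial_out(x, z_x)
    ry = partial_out(y, z_y)
    # a side fully explained by its covariates leaves only rounding noise;
    # the adjusted association is exactly null, not a correlation of noise
    scale_x = np.std(np.asarray(x, float)) or 1.0
    scale_y = np.std(np.asarray(y, float)) or 1.0
    if rx.std() < 1e-12 * scale_x or ry.std() < 1e-12 * scale_y:
        return AssociationResult(
            r=0.0,
            p_nominal=1.0,
            p_corrected=1.0,
            n_tests=int(n_tests),
            n_obs=rx.size,
            sidedness=sidedness,
            adjusted_for=adjusted_for,
        )
    return correlate(rx, ry, sidedness=sidedness, n_tests=n_tests, adjusted_for=adjusted_for)


def nested_poly_ftest(y, age, degree: int, added) -> tuple[float, int, int, float]:
    """F-test of adding one predictor to a degree-``degree`` polynomial model.

    The polynomial basis is centred and orthonormalized (QR) before
    fitting; the test statistic depends only on the spanned subspace.
    Returns (F, df1, df2, p).
    """
    y = np.asarray(y, dtype=float).ravel()
    age = np.asarray(age, dtype=float).ravel()
    added = np.asarray(added, dtype=float).ravel()
    n = y.size
    if age.size != n or added.size != n:
        raise ValueError("all vectors must have equal length")
    if n <= degree + 3:
        raise ValueError("too few observations for the requested degree")

    centred = age - age.mean()
    raw = np.column_stack([centred**d for d in range(1, degree + 1)])
    base = np.column_stack([np.ones(n), raw])
    q_base, r_base = np.linalg.qr(base)
    if np.abs(np.diag(r_base)).min() < 1e-10 * np.abs(np.diag(r_base)).max():
        raise ValueError(
            "polynomial basis is numerically collinear; reduce the degree or rescale age"
        )
    full = np.column_stack([q_base, added])
    if np.linalg.matrix_rank(full) < full.shape[1]:
        raise ValueError("added predictor is collinear with the polynomial basis")

    def rss(design: np.ndarray) -> float:
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        resid = y - design @ coef
        return float(resid @ resid)

    rss0 = rss(q_base)
    rss1 = rss(full)
    df1 = 1
    df2 = n - degree - 2
    if rss1 <= 0:
        raise ValueError("saturated augmented model; F undefined")
    F = (rss0 - rss1) / df1 / (rss1 / df2)
    p = float(stats.f.sf(F, df1, df2))
    return float(F), df1, df2, p
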