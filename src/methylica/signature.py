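"""CpG signatures of components: extraction, genomic context, projection.

A component's signature is the set of CpGs whose loadings lie more than
``n_sigma`` standard deviations from the loadings-row mean. Signatures are
characterized against transcript annotation (TSS / Genic / Intergenic with
strand-aware precedence), compared to background with a chi-squared test,
projected into external cohorts through the pseudo-inverse of the loadings
matrix, and matched across cohorts by hypergeometric set overlap.

Coordinates are 1-based with closed transcript intervals; "upstream" is 5'
of the transcription start on the transcript's strand.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .decompose import ComponentPattern, ICAModel
from .preprocess import BetaMatrix, residualize

logger = logging.getLogger(__name__)

__all__ = [
    "CpGSignature",
    "select_cpgs",
    "classify_context",
    "context_chisq",
    "project",
    "overlap_test",
]

CONTEXT_FLAGS = ("TSS", "Genic", "Intergenic")
TSS_WINDOW = 1500


@dataclass
class CpGSignature:
    component_id: str
    n_sigma: float
    cpg_ids: list[str]
    loadings: np.ndarray
    direction: np.ndarray  # +1 / -1 relative to the loadings-row mean

    @property
    def cpg_set(self) -> frozenset[str]:
        return frozenset(self.cpg_ids)

    def __len__(self) -> int:
        return len(self.cpg_ids)


def select_cpgs(model: ICAModel, component: int | str, n_sigma: float = 4.0) -> CpGSignature:
    """CpGs whose |loading - mean| exceeds ``n_sigma`` loading-row sds."""
    idx = model._index(component)
    row = model.loadings[idx]
    mean = row.mean()
    sd = row.std(ddof=1)
    mask = np.abs(row - mean) > n_sigma * sd
    ids = [c for c, m in zip(model.cpg_ids, mask) if m]
    return CpGSignature(
        component_id=model.component_ids()[idx],
        n_sigma=float(n_sigma),
        cpg_ids=ids,
        loadings=row[mask].copy(),
        direction=np.sign(row[mask] - mean).astype(int),
    )


def classify_context(cpgs: pd.DataFrame, transcripts: pd.DataFrame) -> pd.Series:
    """Flag each CpG as TSS, Genic or Intergenic.

    ``cpgs`` needs columns (cpg_id, chrom, pos); ``transcripts`` needs
    (chrom, start, end, strand) with optional tss (defaults to start for
    '+' and end for '-'). Precedence: a CpG within ``TSS_WINDOW`` bp
    strictly upstream of any transcription start is 'TSS'; otherwise a CpG
    inside any transcript body (closed interval) is 'Genic'; the rest are
    'Intergenic'. CpGs on chromosomes absent from the annotation are
    Intergenic with a warning.
    """
    tr = transcripts.copy()
    if "tss" not in tr.columns:
        tr["tss"] = np.where(tr["strand"] == "+", tr["start"], tr["end"])
    known_chroms = set(tr["chrom"].astype(str))
    missing = sorted(set(cpgs["chrom"].astype(str)) - known_chroms)
    if missing:
        warnings.warn(f"CpGs on unannotated chromosomes flagged Intergenic: {missing}", stacklevel=2)

    flags = []
    by_chrom = {str(c): g for c, g in tr.groupby(tr["chrom"].astype(str))}
    for _, row in cpgs.iterrows():
        chrom = str(row["chrom"])
        pos = int(row["pos"])
        sub = by_chrom.get(chrom)
        if sub is None:
            flags.append("Intergenic")
            continue
        tss = sub["tss"].to_numpy(int)
        strand = sub["strand"].to_numpy(str)
        up_plus = (strand == "+") & (pos >= tss - TSS_WINDOW) & (pos < tss)
        up_minus = (strand == "-") & (pos > tss) & (pos <= tss + TSS_WINDOW)
        if (up_plus | up_minus).any():
            flags.append("TSS")
            continue
        start = sub["start"].to_numpy(int)
        end = sub["end"].to_numpy(int)
        if ((pos >= start) & (pos <= end)).any():
            flags.append("Genic")
        else:
            flags.append("Intergenic")
    return pd.Series(flags, index=cpgs["cpg_id"].astype(str).to_list(), name="context")


def context_chisq(
    signature_contexts: pd.Series,
    background_contexts: pd.Series,
    categories: tuple[str, ...] | None = None,
) -> tuple[float, int, float]:
    """One-sample chi-squared of signature counts vs background proportions."""
    if categories is None:
        categories = tuple(sorted(set(background_contexts)))
    bg_counts = np.array([(background_contexts == c).sum() for c in categories], dtype=float)
    if (bg_counts <= 0).any():
        raise ValueError("all background categories must have positive counts")
    sig_counts = np.array([(signature_contexts == c).sum() for c in categories], dtype=float)
    n = sig_counts.sum()
    expected = n * bg_counts / bg_counts.sum()
    if (expected < 5).any():
        warnings.warn("expected count < 5 in at least one category", stacklevel=2)
    chi2 = float(((sig_counts - expected) ** 2 / expected).sum())
    df = len(categories) - 1
    p = float(stats.chi2.sf(chi2, df))
    return chi2, df, p


def project(
    model: ICAModel,
    component: int | str,
    betas_new: BetaMatrix,
    covariates_new: pd.DataFrame | None = None,
    min_overlap: float = 0.90,
    mode: str = "pinv",
) -> ComponentPattern:
    """Project a trained component into an external beta matrix.

    The new betas are residualized on the supplied covariates and
    standardized per CpG; weights are the residuals times the relevant
    column of the pseudo-inverse of the loadings matrix (mode='pinv'), or
    the normalized loading row itself (mode='single'). Output weights are
    standardized to unit variance. CpGs missing from the new matrix (up to
    1 - min_overlap) are dropped from both sides.
    """
    idx = model._index(component)
    new_ids = set(betas_new.cpg_ids)
    shared = [c for c in model.cpg_ids if c in new_ids]
    frac = len(shared) / len(model.cpg_ids)
    if frac < min_overlap:
        raise ValueError(
            f"only {len(shared)}/{len(model.cpg_ids)} model CpGs present "
            f"({frac:.1%} < {min_overlap:.0%} required)"
        )
    if frac < 1.0:
        logger.info("project: dropping %d model CpGs absent from the target", len(model.cpg_ids) - len(shared))

    resid = residualize(betas_new, covariates_new)
    order = {c: i for i, c in enumerate(resid.cpg_ids)}
    missing_after = [c for c in shared if c not in order]
    shared = [c for c in shared if c in order]
    if missing_after:
        logger.info("project: %d shared CpGs dropped during residualization", len(missing_after))
    cols_new = np.array([order[c] for c in shared])
    R = resid.values[:, cols_new]

    model_order = {c: i for i, c in enumerate(model.cpg_ids)}
    cols_model = np.array([model_order[c] for c in shared])
    S_sub = model.loadings[:, cols_model]

    if mode == "pinv":
        weights = R @ np.linalg.pinv(S_sub)[:, idx]
    elif mode == "single":
        row = S_sub[idx]
        weights = R @ row / (row @ row)
    else:
        raise ValueError("mode must be 'pinv' or 'single'")
    sd = weights.std(ddof=0)
    if sd == 0:
        raise ValueError("projected weights are constant")
    weights = (weights - weights.mean()) / sd
    return ComponentPattern(
        weights=weights,
        component_id=model.component_ids()[idx],
        stability=float(model.stability[idx]),
        dominance=float("nan"),
        sample_ids=list(betas_new.sample_ids),
    )


class OverlapResult(NamedTuple):
    odds_ratio: float  # plain cross-product OR; inf for degenerate tables
    p: float  # one-sided hypergeometric enrichment tail
    odds_ratio_haldane: float  # +0.5-corrected finite estimate


def overlap_test(set_a: set, set_b: set, universe: int) -> OverlapResult:
    """Odds ratio and one-sided hypergeometric enrichment p for set overlap.

    The plain odds ratio is infinite when an off-diagonal cell is empty
    (for example identical sets); the Haldane-Anscombe (+0.5) estimate is
    reported alongside as a finite summary.
    """
    set_a, set_b = set(set_a), set(set_b)
    if not set_a or not set_b:
        raise ValueError("overlap test requires two non-empty sets")
    if len(set_a) > universe or len(set_b) > universe:
        raise ValueError("sets larger than the stated universe")
    a = len(set_a & set_b)
    b = len(set_a) - a
    c = len(set_b) - a
    d = universe - a - b - c
    if d < 0:
        raise ValueError("universe too small for the given sets")
    odds = (a * d) / (b * c) if b * c > 0 else (np.inf if a * d > 0 else np.nan)
    haldane = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    p = float(stats.hypergeom.sf(a - 1, universe, len(set_a), len(set_b)))
    return OverlapResult(float(odds), p, float(haldane))
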