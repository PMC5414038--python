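"""Gene-set enrichment with bias correction.

Two engines: (a) a Wallenius noncentral-hypergeometric test that corrects
CpG-signature enrichment for the number of CpGs mapping to each gene, with
the selection-probability weighting estimated by monotone binned
regression; (b) a percentile-cutoff SNP-score enrichment with a
confounder-adjusted empirical null drawn from random gene sets.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.isotonic import IsotonicRegression

from ._rng import stream

logger = logging.getLogger(__name__)

__all__ = [
    "EnrichmentResult",
    "bh_fdr",
    "read_gmt",
    "goseq_wallenius",
    "percentile_gsea",
]


@dataclass
class EnrichmentResult:
    set_id: str
    n_genes_in_set: int
    statistic: float
    p: float
    fdr: float
    method: str

    def __post_init__(self) -> None:
        # NaN is the not-yet-adjusted placeholder filled by the BH pass
        if not np.isnan(self.fdr) and not 0.0 <= self.fdr <= 1.0:
            raise ValueError("FDR outside [0, 1]")


def bh_fdr(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    # enforce monotonicity from the largest rank down
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    return out


def read_gmt(path) -> dict[str, list[str]]:
    """Parse a GMT file: set name, description, then member genes."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(sets: dict[str, list[str]], path) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, "na", *genes]) + "\n")


def map_cpgs_to_genes(cpgs: pd.DataFrame, transcripts: pd.DataFrame) -> pd.Series:
    """Per-gene CpG counts: a CpG maps to every gene whose transcript
    (body or 1,500 bp upstream window) it touches; multi-mapping allowed.

    ``cpgs`` needs (cpg_id, chrom, pos); ``transcripts`` needs
    (gene_id, chrom, start, end, strand).
    """
    from .signature import TSS_WINDOW

    counts: dict[str, int] = {}
    for chrom, tr_group in transcripts.groupby(transcripts["chrom"].astype(str)):
        sub = cpgs[cpgs["chrom"].astype(str) == chrom]
        if sub.empty:
            for gene in tr_group["gene_id"].astype(str):
                counts.setdefault(gene, 0)
            continue
        pos = sub["pos"].to_numpy(int)
        for _, tr in tr_group.iterrows():
            lo, hi = int(tr["start"]), int(tr["end"])
            if tr["strand"] == "+":
                lo = min(lo, int(tr["start"]) - TSS_WINDOW)
            else:
                hi = max(hi, int(tr["end"]) + TSS_WINDOW)
            n = int(((pos >= lo) & (pos <= hi)).sum())
            gene = str(tr["gene_id"])
            counts[gene] = counts.get(gene, 0) + n
    return pd.Series(counts, dtype=int)


def _selection_weights(selected: np.ndarray, bias: np.ndarray, n_bins: int = 10) -> np.ndarray:
    """Monotone binned estimate of P(selected | bias), floored away from 0."""
    if np.unique(bias).size == 1:
        return np.ones(bias.size)
    ranks = pd.qcut(pd.Series(bias).rank(method="first"), q=min(n_bins, np.unique(bias).size), labels=False)
    ranks = ranks.to_numpy()
    bin_bias = np.array([bias[ranks == b].mean() for b in range(ranks.max() + 1)])
    bin_prob = np.array([selected[ranks == b].mean() for b in range(ranks.max() + 1)])
    iso = IsotonicRegression(increasing=True, out_of_bounds="clip")
    iso.fit(bin_bias, bin_prob)
    w = iso.predict(bias)
    floor = max(selected.mean() * 1e-3, 1e-6)
    return np.maximum(w, floor)


def goseq_wallenius(
    selected_genes: set[str],
    gene_bias: dict[str, int] | pd.Series,
    sets: dict[str, list[str]],
) -> list[EnrichmentResult]:
    """Per-set Wallenius noncentral hypergeometric enrichment.

    ``gene_bias`` gives the per-gene CpG count over the background (every
    background gene must have bias >= 1). The odds parameter for a set is
    the mean estimated selection weight inside the set over the mean
    outside, which reduces to the central (Fisher) test when the bias is
    uniform.
    """
    bias = pd.Series(gene_bias, dtype=float)
    if (bias < 1).any():
        raise ValueError("all background genes must have CpG bias >= 1")
    background = list(map(str, bias.index))
    bg_set = set(background)
    unknown = set(selected_genes) - bg_set
    if unknown:
        raise ValueError(f"selected genes outside the background: {sorted(unknown)[:5]}")
    sel_flag = np.array([g in selected_genes for g in background], dtype=float)
    weights = _selection_weights(sel_flag, bias.to_numpy(float))
    wser = pd.Series(weights, index=background)

    n_total = len(background)
    n_selected = len(selected_genes)
    results = []
    for set_id, genes in sets.items():
        members = sorted(set(genes) & bg_set)
        if not members:
            warnings.warn(f"gene set {set_id!r} has no background genes; skipped", stacklevel=2)
            continue
        others = bg_set - set(members)
        x_obs = len(set(members) & selected_genes)
        m1 = len(members)
        m2 = n_total - m1
        odds = float(wser[members].mean() / wser[list(others)].mean()) if others else 1.0
        dist = stats.nchypergeom_wallenius(n_total, m1, n_selected, odds)
        p = float(dist.sf(x_obs - 1))
        results.append(
            EnrichmentResult(
                set_id=set_id,
                n_genes_in_set=m1,
                statistic=float(x_obs),
                p=min(max(p, 0.0), 1.0),
                fdr=np.nan,
                method="goseq-wallenius",
            )
        )
    _fill_fdr(results)
    return results


def _fill_fdr(results: list[EnrichmentResult]) -> None:
    if not results:
        return
    fdrs = bh_fdr(np.array([r.p for r in results]))
    for r, f in zip(results, fdrs):
        r.fdr = float(f)


def percentile_gsea(
    gene_pvalues: dict[str, float] | pd.Series,
    sets: dict[str, list[str]],
    confounders: pd.DataFrame | None = None,
    cutoff_percentile: float = 75.0,
    n_perm: int = 10_000,
    seed: int = 0,
    min_set_size: int = 20,
    max_set_size: int = 200,
    exclude_genes: set[str] | None = None,
) -> list[EnrichmentResult]:
    """Percentile-cutoff gene-score enrichment with an empirical null.

    The gene score is -log10 of the best-SNP p-value, residualized on the
    confounder table (gene length, SNP count, ...) when given. A set's
    statistic is the count of member genes above the genome-wide
    ``cutoff_percentile``; its p-value is the fraction of equally sized
    random gene draws with at least as many exceedances, floored at
    1/(n_perm + 1). Sets outside [min_set_size, max_set_size] (after
    restriction to scored genes) are skipped.
    """
    pv = pd.Series(gene_pvalues, dtype=float)
    if exclude_genes:
        pv = pv[~pv.index.isin(exclude_genes)]
    genes = list(map(str, pv.index))
    scores = -np.log10(np.clip(pv.to_numpy(float), 1e-300, 1.0))
    if confounders is not None and confounders.shape[1] > 0:
        conf = confounders.loc[pv.index].to_numpy(dtype=float)
        design = np.column_stack([np.ones(len(genes)), conf])
        coef, *_ = np.linalg.lstsq(design, scores, rcond=None)
        scores = scores - design @ coef
    cutoff = np.percentile(scores, cutoff_percentile)
    above = scores > cutoff
    gene_index = {g: i for i, g in enumerate(genes)}

    rng = stream(seed, "percentile-gsea")
    results = []
    for set_id, members in sets.items():
        idx = [gene_index[g] for g in set(members) if g in gene_index]
        size = len(idx)
        if not min_set_size <= size <= max_set_size:
            logger.info("percentile_gsea: set %s size %d outside bounds; skipped", set_id, size)
            continue
        obs = int(above[idx].sum())
        null_draws = np.array(
            [above[rng.choice(len(genes), size=size, replace=False)].sum() for _ in range(n_perm)]
        )
        p = (int((null_draws >= obs).sum()) + 1) / (n_perm + 1)
        results.append(
            EnrichmentResult(
                set_id=set_id,
                n_genes_in_set=size,
                statistic=float(obs),
                p=float(p),
                fdr=np.nan,
                method="percentile-gsea",
            )
        )
    _fill_fdr(results)
    return results
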