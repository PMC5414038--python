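"""Direction-weighted multilocus genetic scores and their meta-analysis.

SNP QC (MAF, exact Hardy-Weinberg, call rate), one top SNP per gene at a
nominal association threshold with +/-1 direction weights, per-sample score
with missingness adjustment, one-sided score-phenotype tests, Stouffer
combination across samples, cis-mQTL window enrichment by permutation, and
per-pair mQTL regression diagnostics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._rng import stream
from .associate import AssociationResult, correlate, partial_out
from .decompose import ComponentPattern
from .preprocess import ResidualMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "GenotypeMatrix",
    "GeneticScoreModel",
    "hwe_exact_test",
    "qc_snps",
    "build_score",
    "score_phenotype_test",
    "stouffer_meta",
    "mqtl_cis_enrichment",
    "mqtl_pair_tests",
]


@dataclass
class GenotypeMatrix:
    """Sample x SNP minor-allele counts; NaN marks a missing genotype."""

    counts: np.ndarray
    sample_ids: list[str]
    snp_ids: list[str]
    gene_map: dict[str, str] = field(default_factory=dict)  # SNP -> gene

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        observed = self.counts[~np.isnan(self.counts)]
        if observed.size and not np.isin(observed, (0.0, 1.0, 2.0)).all():
            raise ValueError("allele counts must be 0, 1, 2 or missing")
        if self.counts.shape != (len(self.sample_ids), len(self.snp_ids)):
            raise ValueError("ID lists do not match matrix shape")

    @property
    def maf(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            freq = np.nanmean(self.counts, axis=0) / 2.0
        return np.minimum(freq, 1.0 - freq)

    @property
    def call_rate(self) -> np.ndarray:
        return 1.0 - np.isnan(self.counts).mean(axis=0)

    def hwe_p(self) -> np.ndarray:
        out = np.empty(len(self.snp_ids))
        for j in range(len(self.snp_ids)):
            col = self.counts[:, j]
            col = col[~np.isnan(col)]
            n_het = int((col == 1).sum())
            n_hom_min = int((col == 2).sum())
            n_hom_maj = int((col == 0).sum())
            if n_hom_min > n_hom_maj:
                n_hom_min, n_hom_maj = n_hom_maj, n_hom_min
            out[j] = hwe_exact_test(n_het, n_hom_min, n_hom_maj)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.sample_ids, columns=self.snp_ids)

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="sample_id", na_rep="NA", float_format="%.0f")

    @classmethod
    def read_tsv(cls, path, gene_map: dict[str, str] | None = None) -> "GenotypeMatrix":
        frame = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
        return cls(
            frame.to_numpy(dtype=float),
            list(map(str, frame.index)),
            list(map(str, frame.columns)),
            gene_map=gene_map or {},
        )


def hwe_exact_test(n_het: int, n_hom_rare: int, n_hom_common: int) -> float:
    """Exact Hardy-Weinberg test (Wigginton-style two-sided probability sum)."""
    n = n_het + n_hom_rare + n_hom_common
    rare = n_het + 2 * n_hom_rare
    if n == 0 or rare == 0:
        return 1.0
    # enumerate heterozygote counts compatible with the allele counts
    het_values = np.arange(rare % 2, min(rare, 2 * n - rare) + 1, 2)
    logprob = np.empty(het_values.size)
    from scipy.special import gammaln

    common = 2 * n - rare
    for i, het in enumerate(het_values):
        hom_r = (rare - het) // 2
        hom_c = (common - het) // 2
        logprob[i] = (
            het * np.log(2.0)
            + gammaln(n + 1)
            - gammaln(het + 1)
            - gammaln(hom_r + 1)
            - gammaln(hom_c + 1)
            + gammaln(rare + 1)
            + gammaln(common + 1)
            - gammaln(2 * n + 1)
        )
    prob = np.exp(logprob - logprob.max())
    prob /= prob.sum()
    obs = prob[het_values == n_het][0]
    return float(prob[prob <= obs * (1 + 1e-12)].sum())


def qc_snps(
    g: GenotypeMatrix,
    maf_min: float = 0.01,
    hwe_p_min: float = 1e-4,
    callrate_min: float = 0.90,
) -> GenotypeMatrix:
    """Remove SNPs failing MAF, exact-HWE or call-rate thresholds."""
    for v in (maf_min, hwe_p_min, callrate_min):
        if not 0.0 <= v <= 1.0:
            raise ValueError("thresholds must lie in [0, 1]")
    keep = (g.maf >= maf_min) & (g.hwe_p() > hwe_p_min) & (g.call_rate >= callrate_min)
    if not keep.any():
        raise ValueError("no SNP survives quality control")
    removed = int((~keep).sum())
    if removed:
        logger.info("qc_snps: removed %d/%d SNPs", removed, keep.size)
    kept_ids = [s for s, k in zip(g.snp_ids, keep) if k]
    return GenotypeMatrix(
        g.counts[:, keep],
        g.sample_ids,
        kept_ids,
        gene_map={s: g.gene_map[s] for s in kept_ids if s in g.gene_map},
    )


@dataclass
class GeneticScoreModel:
    snps: list[str]
    weights: dict[str, int]  # SNP -> +1 / -1
    genes: dict[str, str]  # SNP -> gene
    selection_p_threshold: float
    per_sample_score: np.ndarray  # missingness-adjusted
    raw_score: np.ndarray
    missing_count: np.ndarray
    sample_ids: list[str]
    snp_pvalues: dict[str, float]

    def __post_init__(self) -> None:
        if len(set(self.genes.values())) != len(self.snps):
            raise ValueError("score must contain at most one SNP per gene")
        if any(w not in (1, -1) for w in self.weights.values()):
            raise ValueError("weights must be +1 or -1")


def _snp_association(counts: np.ndarray, target: np.ndarray) -> tuple[float, float]:
    ok = ~np.isnan(counts)
    c = counts[ok]
    t = target[ok]
    if c.size < 3 or c.std(ddof=0) == 0 or t.std(ddof=0) == 0:
        return 0.0, 1.0
    res = stats.pearsonr(c, t)
    return float(res.statistic), float(res.pvalue)


def build_score(
    g: GenotypeMatrix,
    component: ComponentPattern | np.ndarray,
    gene_set: set[str] | None = None,
    p_threshold: float = 0.05,
) -> GeneticScoreModel:
    """One most-significant SNP per gene, +/-1 direction weights.

    Per-SNP additive association against the component weights selects,
    within each gene, the smallest-p SNP below ``p_threshold`` (ties broken
    lexicographically by SNP ID). The weight is the sign of the minor
    allele's effect so that the training score-component correlation is
    non-negative by construction. If one SNP is the top marker of several
    genes in the set, only the gene with the stronger signal is kept. The
    per-sample score is the weighted allele-count sum over non-missing
    SNPs, residualized on the per-sample count of missing score SNPs.
    """
    target = component.weights if isinstance(component, ComponentPattern) else np.asarray(component, float)
    if target.size != len(g.sample_ids):
        raise ValueError("component weights not aligned to genotype samples")

    candidates: dict[str, tuple[float, str, float]] = {}  # gene -> (p, snp, r)
    for j, snp in enumerate(g.snp_ids):
        gene = g.gene_map.get(snp)
        if gene is None or (gene_set is not None and gene not in gene_set):
            continue
        r, p = _snp_association(g.counts[:, j], target)
        if p >= p_threshold or r == 0.0:
            continue
        best = candidates.get(gene)
        if best is None or (p, snp) < (best[0], best[1]):
            candidates[gene] = (p, snp, r)

    if not candidates:
        raise ValueError("no SNP qualifies in any gene of the set")

    # within-set proximity pruning: one SNP topping several genes keeps only
    # the gene with the stronger (smaller-p) signal
    by_snp: dict[str, tuple[float, str, float]] = {}
    for gene, (p, snp, r) in candidates.items():
        cur = by_snp.get(snp)
        if cur is None or (p, gene) < (cur[0], cur[1]):
            by_snp[snp] = (p, gene, r)

    snps = sorted(by_snp)
    weights = {snp: (1 if by_snp[snp][2] > 0 else -1) for snp in snps}
    genes = {snp: by_snp[snp][1] for snp in snps}
    pvals = {snp: by_snp[snp][0] for snp in snps}

    idx = [g.snp_ids.index(s) for s in snps]
    sub = g.counts[:, idx]
    w = np.array([weights[s] for s in snps], dtype=float)
    filled = np.where(np.isnan(sub), 0.0, sub)
    raw = filled @ w
    missing = np.isnan(sub).sum(axis=1).astype(float)
    if missing.std(ddof=0) > 0:
        adjusted = partial_out(raw, missing)
    else:
        adjusted = raw - raw.mean()
    return GeneticScoreModel(
        snps=snps,
        weights=weights,
        genes=genes,
        selection_p_threshold=p_threshold,
        per_sample_score=adjusted,
        raw_score=raw,
        missing_count=missing,
        sample_ids=list(g.sample_ids),
        snp_pvalues=pvals,
    )


def score_phenotype_test(
    score: np.ndarray | GeneticScoreModel,
    phenotype: np.ndarray,
    sidedness: str = "two-sided",
    n_tests: int = 1,
) -> AssociationResult:
    """Pearson test of score vs phenotype, optionally one-sided."""
    vec = score.per_sample_score if isinstance(score, GeneticScoreModel) else np.asarray(score, float)
    return correlate(vec, phenotype, sidedness=sidedness, n_tests=n_tests)


def stouffer_meta(
    results: list[tuple[float, int, float]],
    weighting: str = "sqrt_n",
) -> tuple[float, float]:
    """Stouffer combination of one-sided p-values and n-weighted mean r.

    ``results`` holds (r, n, p_one_sided) per study. Weights are sqrt(n)
    (default), n, or none; combined Z = sum(w Z) / sqrt(sum w^2); the
    weighted mean correlation always uses n-weights.
    """
    if len(results) < 2 and len(results) != 1:
        raise ValueError("need at least one study")
    rs = np.array([r for r, _, _ in results], dtype=float)
    ns = np.array([n for _, n, _ in results], dtype=float)
    ps = np.array([p for _, _, p in results], dtype=float)
    clipped = np.clip(ps, 1e-300, 1.0 - 1e-16)
    if (clipped != ps).any():
        logger.warning("stouffer_meta: degenerate p-values clipped")
    z = stats.norm.isf(clipped)
    if weighting == "sqrt_n":
        w = np.sqrt(ns)
    elif weighting == "n":
        w = ns
    elif weighting == "none":
        w = np.ones_like(ns)
    else:
        raise ValueError("weighting must be 'sqrt_n', 'n' or 'none'")
    z_comb = float((w * z).sum() / np.sqrt((w**2).sum()))
    p_comb = float(stats.norm.sf(z_comb))
    weighted_r = float((ns * rs).sum() / ns.sum())
    return p_comb, weighted_r


def mqtl_cis_enrichment(
    snp_positions: pd.DataFrame,
    cpg_positions: pd.DataFrame,
    genome: dict[str, int],
    window: int = 1_000_000,
    n_perm: int = 10_000,
    seed: int = 0,
) -> tuple[float, float]:
    """Fraction of SNPs within +/-window of any signature CpG, permutation p.

    Both position tables need (chrom, pos) columns. The null re-places each
    SNP uniformly over the genome; the p-value carries the 1/(n_perm + 1)
    floor.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    chroms = sorted(genome)
    lengths = np.array([genome[c] for c in chroms], dtype=float)
    cpg_by_chrom = {
        str(c): np.sort(grp["pos"].to_numpy(float)) for c, grp in cpg_positions.groupby("chrom")
    }

    def cis_fraction(chrom_arr: np.ndarray, pos_arr: np.ndarray) -> float:
        hits = 0
        for chrom, pos in zip(chrom_arr, pos_arr):
            cpgs = cpg_by_chrom.get(str(chrom))
            if cpgs is None or cpgs.size == 0:
                continue
            i = np.searchsorted(cpgs, pos)
            near = False
            if i < cpgs.size and abs(cpgs[i] - pos) <= window:
                near = True
            if i > 0 and abs(cpgs[i - 1] - pos) <= window:
                near = True
            hits += near
        return hits / len(pos_arr)

    observed = cis_fraction(
        snp_positions["chrom"].to_numpy(), snp_positions["pos"].to_numpy(float)
    )

    rng = stream(seed, "cis-enrichment")
    n_snps = len(snp_positions)
    probs = lengths / lengths.sum()
    exceed = 0
    for _ in range(n_perm):
        chrom_idx = rng.choice(len(chroms), size=n_snps, p=probs)
        pos = rng.integers(1, lengths[chrom_idx].astype(int) + 1)
        frac = cis_fraction(np.array(chroms)[chrom_idx], pos.astype(float))
        if frac >= observed:
            exceed += 1
    p = (exceed + 1) / (n_perm + 1)
    return float(observed), float(p)


def mqtl_pair_tests(
    g: GenotypeMatrix,
    residuals: ResidualMatrix,
    pairs: list[tuple[str, str]],
) -> pd.DataFrame:
    """Per-pair additive regression of CpG residuals on allele counts.

    Returns a table (snp, cpg, beta, p) plus a uniform-null KS diagnostic
    in ``DataFrame.attrs['ks']``. Monomorphic SNPs are skipped with a
    logged warning.
    """
    snp_idx = {s: j for j, s in enumerate(g.snp_ids)}
    cpg_idx = {c: j for j, c in enumerate(residuals.cpg_ids)}
    rows = []
    for snp, cpg in pairs:
        if snp not in snp_idx or cpg not in cpg_idx:
            raise KeyError(f"unknown pair ({snp}, {cpg})")
        counts = g.counts[:, snp_idx[snp]]
        meth = residuals.values[:, cpg_idx[cpg]]
        ok = ~np.isnan(counts)
        c, v = counts[ok], meth[ok]
        if c.std(ddof=0) == 0:
            logger.warning("mqtl_pair_tests: monomorphic SNP %s skipped", snp)
            continue
        slope, _, r, p, _ = stats.linregress(c, v)
        rows.append({"snp": snp, "cpg": cpg, "beta": slope, "p": p})
    table = pd.DataFrame(rows, columns=["snp", "cpg", "beta", "p"])
    if len(table):
        ks = stats.kstest(table["p"].to_numpy(), "uniform")
        table.attrs["ks"] = {"statistic": float(ks.statistic), "p": float(ks.pvalue)}
    return table
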