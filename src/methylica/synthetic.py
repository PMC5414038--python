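"""Synthetic fixtures with the statistical structure the pipeline assumes.

Generates a beta-value methylome driven by sparse heavy-tailed latent
components, a phenotype table in which one component carries an age signal
and partially mediates an age -> cortical-thickness effect, a regional
thickness factor structure, CpG/transcript annotation on a toy genome, and
genotypes with cis-mQTL effects on the age-loaded component.

All randomness flows from ``design.seed`` through labelled sub-streams, so
each stage is independently reproducible.

The three correlation targets are interpreted as *marginal* Pearson
correlations of (age, component), (component, thickness) and
(age, thickness); the generator solves for the partial path coefficients
internally and the implied 3x3 correlation matrix must be positive
semidefinite.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from ._rng import stream
from .preprocess import BetaMatrix

__all__ = [
    "SyntheticDesign",
    "TruthRecord",
    "generate_methylome",
    "generate_phenotypes",
    "generate_annotation",
    "generate_genotypes",
    "simulate",
]

# Pearson correlation between U = Phi(Z1) and Z2 for bivariate normal
# (Z1, Z2) with correlation rho is rho * sqrt(3/pi); invert it so the
# uniform-age construction hits the requested marginal correlation.
_COPULA_ATTENUATION = float(np.sqrt(3.0 / np.pi))


@dataclass
class SyntheticDesign:
    n_samples: int = 200
    n_cpgs: int = 2000
    n_components: int = 3
    sparsity: float = 0.02
    loading_scale: float = 4.0
    signal_scale: float = 0.1  # logit-units of methylation shift per signal unit
    age_component_index: int = 1
    r_age_component: float = 0.29
    r_component_thickness: float = -0.24
    r_age_thickness: float = -0.27
    r_component_memory: float = -0.14
    r_component_region_factor: float = -0.30
    n_factors_regions: int = 4
    n_regions: int = 68
    region_noise_sd: float = 1.0
    n_snps: int = 60
    cis_fraction: float = 0.5
    maf_range: tuple[float, float] = (0.05, 0.45)
    mqtl_effect: float = 0.3
    genotype_missing_rate: float = 0.02
    noise_sd: float = 0.5
    n_batches: int = 1
    batch_effect_sd: float = 0.0
    age_range: tuple[float, float] = (18.0, 35.0)
    n_chromosomes: int = 4
    chromosome_length: int = 10_000_000
    n_transcripts: int = 120
    seed: int = 0

    def validate(self) -> None:
        counts = {
            "n_samples": self.n_samples,
            "n_cpgs": self.n_cpgs,
            "n_components": self.n_components,
            "n_factors_regions": self.n_factors_regions,
            "n_regions": self.n_regions,
            "n_snps": self.n_snps,
            "n_chromosomes": self.n_chromosomes,
            "n_transcripts": self.n_transcripts,
        }
        for name, value in counts.items():
            if value <= 0:
                raise ValueError(f"{name} must be positive")
        for name, value in {"sparsity": self.sparsity, "cis_fraction": self.cis_fraction}.items():
            if not 0.0 < value < 1.0:
                raise ValueError(f"{name} must lie in (0, 1)")
        for name, value in {
            "r_age_component": self.r_age_component,
            "r_component_thickness": self.r_component_thickness,
            "r_age_thickness": self.r_age_thickness,
        }.items():
            if not -1.0 < value < 1.0:
                raise ValueError(f"{name} must lie in (-1, 1)")
        if not 0 <= self.age_component_index < self.n_components:
            raise ValueError("age_component_index out of range")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("MAF range must lie within (0, 0.5]")
        corr = self.correlation_matrix()
        if np.linalg.eigvalsh(corr).min() < -1e-10:
            raise ValueError(
                "correlation targets (age-component, component-thickness, "
                "age-thickness) imply a non-PSD 3x3 correlation matrix"
            )

    def correlation_matrix(self) -> np.ndarray:
        """Implied (age, component, thickness) correlation matrix."""
        r_ac, r_ct, r_at = (
            self.r_age_component,
            self.r_component_thickness,
            self.r_age_thickness,
        )
        return np.array([[1, r_ac, r_at], [r_ac, 1, r_ct], [r_at, r_ct, 1]], dtype=float)

    def path_coefficients(self) -> tuple[float, float, float]:
        """(b, c_prime, noise_sd) for thickness = c'*age + b*component + e."""
        r_ac, r_ct, r_at = (
            self.r_age_component,
            self.r_component_thickness,
            self.r_age_thickness,
        )
        denom = 1.0 - r_ac**2
        b = (r_ct - r_ac * r_at) / denom
        c_prime = (r_at - r_ac * r_ct) / denom
        var = 1.0 - (b**2 + c_prime**2 + 2.0 * b * c_prime * r_ac)
        if var < -1e-10:
            raise ValueError("correlation targets leave no room for noise (non-PSD)")
        return b, c_prime, float(np.sqrt(max(var, 0.0)))


@dataclass
class TruthRecord:
    mixing: np.ndarray  # n x k true sample weights
    loadings: np.ndarray  # k x p true sparse loadings
    active_sets: list[list[int]]  # CpG indices with non-null loading per component
    age_component_index: int
    baselines: np.ndarray  # per-CpG logit baselines
    batch: np.ndarray  # per-sample batch labels
    regional_factor_scores: np.ndarray | None = None  # n x f
    regional_loadings: np.ndarray | None = None  # regions x f
    region_factor_assignment: np.ndarray | None = None
    causal_snps: list[str] = field(default_factory=list)

    def component_weights(self, index: int | None = None) -> np.ndarray:
        idx = self.age_component_index if index is None else index
        return self.mixing[:, idx]

    def write_json(self, path) -> None:
        payload = {
            "mixing": self.mixing.tolist(),
            "loadings": self.loadings.tolist(),
            "active_sets": [list(map(int, s)) for s in self.active_sets],
            "age_component_index": int(self.age_component_index),
            "baselines": self.baselines.tolist(),
            "batch": self.batch.tolist(),
            "regional_factor_scores": None
            if self.regional_factor_scores is None
            else self.regional_factor_scores.tolist(),
            "regional_loadings": None
            if self.regional_loadings is None
            else self.regional_loadings.tolist(),
            "region_factor_assignment": None
            if self.region_factor_assignment is None
            else self.region_factor_assignment.tolist(),
            "causal_snps": self.causal_snps,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def read_json(cls, path) -> "TruthRecord":
        payload = json.loads(Path(path).read_text())
        return cls(
            mixing=np.asarray(payload["mixing"], dtype=float),
            loadings=np.asarray(payload["loadings"], dtype=float),
            active_sets=[list(map(int, s)) for s in payload["active_sets"]],
            age_component_index=int(payload["age_component_index"]),
            baselines=np.asarray(payload["baselines"], dtype=float),
            batch=np.asarray(payload["batch"], dtype=int),
            regional_factor_scores=None
            if payload["regional_factor_scores"] is None
            else np.asarray(payload["regional_factor_scores"], dtype=float),
            regional_loadings=None
            if payload["regional_loadings"] is None
            else np.asarray(payload["regional_loadings"], dtype=float),
            region_factor_assignment=None
            if payload["region_factor_assignment"] is None
            else np.asarray(payload["region_factor_assignment"], dtype=int),
            causal_snps=list(payload["causal_snps"]),
        )


def _standardize_columns(mat: np.ndarray) -> np.ndarray:
    return (mat - mat.mean(axis=0)) / mat.std(axis=0, ddof=0)


def gaussian_with_exact_correlations(corr: np.ndarray, n: int, seed: int = 0) -> np.ndarray:
    """Draw an n x d matrix whose *empirical* correlations equal ``corr``.

    A raw Gaussian draw is empirically whitened and recoloured with the
    Cholesky factor of the target matrix, so the sample correlation matrix
    matches the target exactly (up to floating point). Used to turn a
    printed correlation structure into a concrete dataset.
    """
    corr = np.asarray(corr, dtype=float)
    d = corr.shape[0]
    if n <= d:
        raise ValueError("need n > d observations")
    if np.linalg.eigvalsh(corr).min() < -1e-12:
        raise ValueError("target correlation matrix is not PSD")
    rng = stream(seed, "exact-correlations")
    Z = rng.standard_normal((n, d))
    Z -= Z.mean(axis=0)
    cov = Z.T @ Z / n
    # K K^T = cov^-1, so (Z K)^T (Z K) / n = K^T cov K = I exactly
    white = Z @ np.linalg.cholesky(np.linalg.inv(cov))
    return white @ np.linalg.cholesky(corr).T


def generate_methylome(design: SyntheticDesign) -> tuple[BetaMatrix, TruthRecord]:
    """Beta matrix from sparse heavy-tailed components through a logistic map.

    Per-CpG logit baselines come from a hypo/hemi/hyper mixture so the
    marginal beta distribution is bimodal, like array data. Active
    loadings are two-sided |N(loading_scale, 1)| draws so a 4-sigma
    selection rule has a planted positive set.
    """
    design.validate()
    rng = stream(design.seed, "methylome")
    n, p, k = design.n_samples, design.n_cpgs, design.n_components

    A = _standardize_columns(rng.standard_normal((n, k)))
    n_active = max(1, round(design.sparsity * p))
    S = np.zeros((k, p))
    active_sets = []
    for j in range(k):
        active = rng.choice(p, size=n_active, replace=False)
        signs = rng.choice([-1.0, 1.0], size=n_active)
        magnitude = np.abs(rng.normal(design.loading_scale, 1.0, size=n_active))
        S[j, active] = signs * magnitude
        active_sets.append(sorted(map(int, active)))

    mixture = rng.choice(3, size=p, p=[0.4, 0.2, 0.4])
    centers = np.array([-2.5, 0.0, 2.5])
    baselines = rng.normal(centers[mixture], 0.5)

    batch = rng.integers(0, design.n_batches, size=n)
    batch_shift = np.zeros((n, p))
    if design.n_batches > 1 and design.batch_effect_sd > 0:
        effects = rng.normal(0.0, design.batch_effect_sd, size=(design.n_batches, p))
        batch_shift = effects[batch]

    noise = rng.normal(0.0, design.noise_sd, size=(n, p)) if design.noise_sd > 0 else 0.0
    logits = baselines[None, :] + design.signal_scale * (A @ S + noise) + batch_shift
    betas = 1.0 / (1.0 + np.exp(-logits))

    truth = TruthRecord(
        mixing=A,
        loadings=S,
        active_sets=active_sets,
        age_component_index=design.age_component_index,
        baselines=baselines,
        batch=batch,
    )
    sample_ids = [f"s{i + 1:04d}" for i in range(n)]
    cpg_ids = [f"cg{j + 1:07d}" for j in range(p)]
    return BetaMatrix(betas, sample_ids, cpg_ids), truth


def generate_phenotypes(design: SyntheticDesign, truth: TruthRecord) -> pd.DataFrame:
    """Phenotype/covariate table tied to the age-loaded component.

    Age is uniform over ``design.age_range`` via a Gaussian copula whose
    latent correlation is inflated by sqrt(pi/3) so the *observed* age-
    component Pearson correlation matches the target. Thickness is built
    from standardized observed age and the true component weights with
    path coefficients solved from the marginal targets, so all three
    marginal correlations hit their targets in expectation. Regional
    thickness columns follow an orthogonal factor model with one factor
    loaded on the mediating component; the memory score loads negatively
    on the component. The truth record is extended in place with the
    regional factor structure.
    """
    design.validate()
    rng = stream(design.seed, "phenotypes")
    n = design.n_samples
    comp = _standardize_columns(truth.component_weights()[:, None])[:, 0]

    rho = design.r_age_component / _COPULA_ATTENUATION
    if abs(rho) >= 1.0:
        raise ValueError("r_age_component too large for the uniform-age construction")
    age_latent = rho * comp + np.sqrt(1.0 - rho**2) * rng.standard_normal(n)
    age_u = stats.norm.cdf(age_latent)
    lo, hi = design.age_range
    age_main = lo + (hi - lo) * age_u
    age_blood = age_main + rng.uniform(0.0, 2.0, size=n)

    age_std = _standardize_columns(age_main[:, None])[:, 0]
    b, c_prime, sd_noise = design.path_coefficients()
    thickness = c_prime * age_std + b * comp + sd_noise * rng.standard_normal(n)

    f = design.n_factors_regions
    factors = rng.standard_normal((n, f))
    lam = design.r_component_region_factor
    factors[:, f - 1] = lam * comp + np.sqrt(1.0 - lam**2) * rng.standard_normal(n)
    factors = _standardize_columns(factors)

    n_regions = design.n_regions
    assignment = np.arange(n_regions) % f
    loading_mag = rng.uniform(0.6, 0.8, size=n_regions)
    regional = np.empty((n, n_regions))
    for r in range(n_regions):
        lam_r = loading_mag[r]
        noise_r = design.region_noise_sd * np.sqrt(1.0 - lam_r**2)
        regional[:, r] = lam_r * factors[:, assignment[r]] + noise_r * rng.standard_normal(n)

    r_em = design.r_component_memory
    memory = r_em * comp + np.sqrt(1.0 - r_em**2) * rng.standard_normal(n)

    table = pd.DataFrame(
        {
            "age_blood": age_blood,
            "age_main": age_main,
            "sex": rng.integers(0, 2, size=n),
            "batch": truth.batch,
            "thickness_global": thickness,
            "memory": memory,
            "lymphocytes": rng.normal(2.0, 0.5, size=n),
            "neutrophils": rng.normal(4.0, 1.0, size=n),
            "mixed_cells": rng.normal(0.8, 0.2, size=n),
            "smoking": rng.integers(0, 5, size=n),
            "alcohol": rng.integers(0, 3, size=n),
            "cannabis": rng.integers(0, 3, size=n),
            "bmi": rng.normal(23.0, 3.0, size=n),
        },
        index=[f"s{i + 1:04d}" for i in range(n)],
    )
    for r in range(n_regions):
        table[f"region{r + 1:02d}"] = regional[:, r]

    truth.regional_factor_scores = factors
    truth.regional_loadings = np.array(
        [[loading_mag[r] if assignment[r] == j else 0.0 for j in range(f)] for r in range(n_regions)]
    )
    truth.region_factor_assignment = assignment
    return table


def generate_annotation(design: SyntheticDesign) -> tuple[pd.DataFrame, pd.DataFrame]:
    """CpG and transcript annotation on a toy multi-chromosome genome.

    Positions are 1-based; transcript intervals are closed; TSS is the
    start for '+' transcripts and the end for '-' transcripts.
    """
    design.validate()
    rng = stream(design.seed, "annotation")
    p = design.n_cpgs
    chroms = rng.integers(1, design.n_chromosomes + 1, size=p)
    positions = rng.integers(1, design.chromosome_length + 1, size=p)
    island = rng.choice(
        ["Island", "Shore", "Shelf", "OpenSea"], size=p, p=[0.3, 0.25, 0.15, 0.3]
    )
    cpgs = pd.DataFrame(
        {
            "cpg_id": [f"cg{j + 1:07d}" for j in range(p)],
            "chrom": chroms.astype(str),
            "pos": positions,
            "island_context": island,
        }
    )

    t = design.n_transcripts
    t_chrom = rng.integers(1, design.n_chromosomes + 1, size=t)
    length = rng.integers(2_000, 50_001, size=t)
    start = rng.integers(1, design.chromosome_length - length + 1)
    strand = rng.choice(["+", "-"], size=t)
    transcripts = pd.DataFrame(
        {
            "gene_id": [f"gene{j + 1:04d}" for j in range(t)],
            "transcript_id": [f"tx{j + 1:04d}" for j in range(t)],
            "chrom": t_chrom.astype(str),
            "start": start,
            "end": start + length - 1,
            "strand": strand,
        }
    )
    transcripts["tss"] = np.where(
        transcripts["strand"] == "+", transcripts["start"], transcripts["end"]
    )
    return cpgs, transcripts


def generate_genotypes(
    design: SyntheticDesign,
    truth: TruthRecord,
    annotation: pd.DataFrame,
    transcripts: pd.DataFrame | None = None,
):
    """Genotypes with cis-mQTL effects on the age-loaded component.

    A ``cis_fraction`` of SNPs is placed within +/-1 Mbp of active CpGs of
    the age-loaded component and made causal: each minor allele shifts the
    component weight by ``mqtl_effect`` (in sd units), realized by drawing
    alleles from a liability threshold conditioned on the observed
    component weights so the marginal MAF is preserved. Returns the
    genotype matrix and a SNP table (snp_id, chrom, pos, gene).
    """
    from .genescore import GenotypeMatrix

    design.validate()
    rng = stream(design.seed, "genotypes")
    n, m = design.n_samples, design.n_snps
    lo, hi = design.maf_range
    mafs = rng.uniform(lo, hi, size=m)
    comp = _standardize_columns(truth.component_weights()[:, None])[:, 0]

    active = truth.active_sets[truth.age_component_index]
    ann = annotation.set_index("cpg_id")
    cpg_ids = [f"cg{j + 1:07d}" for j in active]
    active_pos = ann.loc[cpg_ids, ["chrom", "pos"]]

    n_cis = int(round(design.cis_fraction * m))
    chrom_arr = np.empty(m, dtype=object)
    pos_arr = np.empty(m, dtype=int)
    for j in range(m):
        if j < n_cis:
            row = active_pos.iloc[rng.integers(0, len(active_pos))]
            offset = int(rng.integers(-1_000_000, 1_000_001))
            chrom_arr[j] = str(row["chrom"])
            pos_arr[j] = int(np.clip(int(row["pos"]) + offset, 1, design.chromosome_length))
        else:
            chrom_arr[j] = str(rng.integers(1, design.n_chromosomes + 1))
            pos_arr[j] = int(rng.integers(1, design.chromosome_length + 1))

    counts = np.empty((n, m))
    causal = []
    for j in range(m):
        maf = mafs[j]
        if j < n_cis and design.mqtl_effect != 0.0:
            thresh = stats.norm.isf(maf)
            delta = design.mqtl_effect * maf * (1.0 - maf) / stats.norm.pdf(thresh)
            delta = float(np.clip(delta, 0.0, 0.99))
            z = delta * comp[:, None] + np.sqrt(1.0 - delta**2) * rng.standard_normal((n, 2))
            counts[:, j] = (z > thresh).sum(axis=1)
            causal.append(j)
        else:
            counts[:, j] = rng.binomial(2, maf, size=n)
            if j < n_cis:
                causal.append(j)

    if design.genotype_missing_rate > 0:
        mask = rng.random((n, m)) < design.genotype_missing_rate
        counts[mask] = np.nan

    snp_ids = [f"rs{j + 1:05d}" for j in range(m)]
    # map each SNP to the gene of the nearest transcript TSS on its chromosome
    gene_map: dict[str, str] = {}
    if transcripts is not None:
        for j, snp in enumerate(snp_ids):
            sub = transcripts[transcripts["chrom"] == chrom_arr[j]]
            if len(sub):
                nearest = (sub["tss"] - pos_arr[j]).abs().idxmin()
                gene_map[snp] = str(sub.loc[nearest, "gene_id"])
            else:
                gene_map[snp] = f"gene_orphan_{j}"
    else:
        gene_map = {snp: f"gene_snp{j + 1:04d}" for j, snp in enumerate(snp_ids)}

    snp_table = pd.DataFrame(
        {
            "snp_id": snp_ids,
            "chrom": chrom_arr.astype(str),
            "pos": pos_arr,
            "gene": [gene_map[s] for s in snp_ids],
        }
    )
    matrix = GenotypeMatrix(
        counts,
        [f"s{i + 1:04d}" for i in range(n)],
        snp_ids,
        gene_map=gene_map,
    )
    truth.causal_snps = [snp_ids[j] for j in causal]
    return matrix, snp_table


def simulate(design: SyntheticDesign, outdir) -> dict[str, Path]:
    """Generate the full fixture set and write plain-text files to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    betas, truth = generate_methylome(design)
    phenotypes = generate_phenotypes(design, truth)
    cpgs, transcripts = generate_annotation(design)
    genotypes, snp_table = generate_genotypes(design, truth, cpgs, transcripts)

    # toy gene-set collection over the transcript genes, for enrichment runs
    rng = stream(design.seed, "gene-sets")
    genes = transcripts["gene_id"].astype(str).to_list()
    gene_sets = {}
    for i in range(5):
        size = int(rng.integers(20, min(41, len(genes))))
        gene_sets[f"set{i + 1}"] = sorted(rng.choice(genes, size=size, replace=False))

    paths = {
        "betas": outdir / "betas.tsv",
        "gene_sets": outdir / "gene_sets.gmt",
        "phenotypes": outdir / "phenotypes.tsv",
        "cpg_annotation": outdir / "cpg_annotation.tsv",
        "transcripts": outdir / "transcripts.tsv",
        "genotypes": outdir / "genotypes.tsv",
        "snps": outdir / "snps.tsv",
        "truth": outdir / "truth.json",
    }
    betas.write_tsv(paths["betas"])
    phenotypes.to_csv(paths["phenotypes"], sep="\t", index_label="sample_id", float_format="%.10g")
    cpgs.to_csv(paths["cpg_annotation"], sep="\t", index=False)
    transcripts.to_csv(paths["transcripts"], sep="\t", index=False)
    genotypes.write_tsv(paths["genotypes"])
    snp_table.to_csv(paths["snps"], sep="\t", index=False)
    truth.write_json(paths["truth"])
    from .enrichment import write_gmt

    write_gmt(gene_sets, paths["gene_sets"])
    return paths
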