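# methylica

Decomposition of whole-blood DNA-methylation profiles into latent
components and association of those components with phenotypes.

The pipeline: a sample × CpG beta-value matrix is filtered, imputed,
adjusted for known covariates plus surrogate variables (protecting a
designated covariate such as age), and standardized per CpG. The residual
matrix is decomposed by multi-restart FastICA with the component count
chosen by a Marchenko–Pastur (random-matrix) edge rule; restarts are pooled
and clustered (complete linkage on 1 − |r|) and each final component is the
centrotype of its cluster. Components dominated by single samples are
filtered out. Retained components are tested against phenotypes (Pearson
tests with explicit Bonferroni families, asymmetric covariate partialling,
a nested polynomial-age F-test), fed into a three-variable mediation
analysis with kappa-squared effect size and BCa bootstrap CIs, reduced to
CpG signatures (n-sigma loading threshold) with genomic-context
classification and cross-cohort projection, and linked to regional
thickness factors (parallel analysis, principal-axis factoring, varimax,
regression scores) and to direction-weighted multilocus genetic scores with
Stouffer meta-analysis, cis-mQTL enrichment and bias-corrected gene-set
enrichment (Wallenius / percentile-cutoff GSEA).

A synthetic-data module generates the full fixture set (methylome,
phenotypes, annotation, genotypes) with planted components, a mediation
triple, a regional factor structure and cis-mQTL effects, so every stage is
testable offline.

## Test

```sh
python -m pytest tests/                 # default: fast suite
python -m pytest -o addopts= tests/     # everything, incl. slow calibration
```

`tests/test_acceptance.py` holds the acceptance criteria (desk-scale
arithmetic reproduced from in-text values plus seeded property checks:
planted-component recovery, projection round-trips, bootstrap calibration,
enrichment oracles).

## CLI

```sh
# generate a synthetic fixture set
methylica simulate --out data/ --seed 1

# preprocess a beta matrix (covariate TSV must contain the protected column)
methylica preprocess --betas data/betas.tsv --covariates data/phenotypes.tsv \
    --protect age_blood --n-sv auto --out residuals.tsv

# decompose (k chosen by RMT when --k auto)
methylica decompose --residuals residuals.tsv --k auto --restarts 30 \
    --dominance 0.10 --seed 1 --out decomp/

# mediation with BCa bootstrap
methylica mediate --phenotypes data/phenotypes.tsv --weights decomp/weights.tsv \
    --m IC2 --boot 10000 --seed 1

# full pipeline on synthetic data
methylica pipeline --simulate --out run/ --seed 1

# full pipeline from a config file
methylica pipeline --config run.cfg --out run/
```

Config files are INI-style; every key of `methylica.pipeline.PipelineConfig`
is accepted, e.g.

```ini
[inputs]
betas = data/betas.tsv
phenotypes = data/phenotypes.tsv
genotypes = data/genotypes.tsv
snps = data/snps.tsv

[decompose]
k = auto
n_restarts = 30
dominance_threshold = 0.10
```

## Layout

```
src/methylica/
  synthetic.py    fixture generator (design, truth record, writers)
  preprocess.py   filtering, kNN imputation, surrogates, residualization
  decompose.py    RMT order selection, FastICA restarts, centrotypes, dominance
  associate.py    Pearson tests, Bonferroni, partialling, nested poly F-test
  mediate.py      paths, kappa-squared, BCa bootstrap
  signature.py    n-sigma CpG selection, genomic context, projection, overlap
  efa.py          parallel analysis, principal-axis factoring, varimax, scores
  genescore.py    SNP QC, direction-weighted scores, Stouffer, cis-mQTL
  enrichment.py   Wallenius (CpG-bias corrected) and percentile-cutoff GSEA
  pipeline.py     end-to-end driver, config, run manifest
  cli.py          click entry points
```
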