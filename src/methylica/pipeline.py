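"""End-to-end pipeline driver with config parsing and run manifests."""

from __future__ import annotations

import configparser
import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import associate, decompose, efa, genescore, mediate, preprocess, signature, synthetic

logger = logging.getLogger(__name__)

__all__ = ["RunManifest", "PipelineConfig", "run_pipeline", "simulate_and_run"]


@dataclass
class PipelineConfig:
    betas: str
    phenotypes: str
    seed: int = 0
    max_missing: float = 0.05
    knn_k: int = 10
    n_sv: str | int = "auto"
    protect: str = "age_blood"
    sex_column: str = "sex"
    k: str | int = "auto"
    n_restarts: int = 30
    dominance_threshold: float = 0.10
    n_sigma: float = 4.0
    n_tests_components: int | None = None  # default: number of retained components
    n_tests_factors: int | None = None  # default: parallel-analysis factor count
    age_blood: str = "age_blood"
    age_main: str = "age_main"
    thickness: str = "thickness_global"
    memory: str = "memory"
    region_prefix: str = "region"
    n_boot: int = 2000
    ci_level: float = 0.999
    stouffer_weighting: str = "sqrt_n"
    run_efa: bool = True
    run_mediation: bool = True
    genotypes: str | None = None
    snps: str | None = None
    cpg_annotation: str | None = None
    transcripts: str | None = None
    gene_sets: str | None = None

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        parser = configparser.ConfigParser()
        parser.read(path)
        raw: dict = {}
        for section in parser.sections():
            raw.update(dict(parser[section]))
        kwargs = {}
        for key, value in raw.items():
            if key not in cls.__dataclass_fields__:
                raise KeyError(f"unknown config key: {key}")
            target = cls.__dataclass_fields__[key].type
            if key in ("n_sv", "k"):
                kwargs[key] = value if value == "auto" else int(value)
            elif value.lower() in ("true", "false"):
                kwargs[key] = value.lower() == "true"
            else:
                try:
                    kwargs[key] = int(value)
                except ValueError:
                    try:
                        kwargs[key] = float(value)
                    except ValueError:
                        kwargs[key] = value
        return cls(**kwargs)


@dataclass
class RunManifest:
    config: dict
    seed: int
    input_digests: dict
    stages: dict = field(default_factory=dict)

    def record(self, stage: str, **params) -> None:
        self.stages[stage] = params

    def write_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, default=str))


def _digest(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()[:16]


def run_pipeline(config: PipelineConfig, outdir) -> RunManifest:
    """preprocess -> decompose -> associate -> mediate -> signature -> EFA -> genescore."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    inputs = {"betas": config.betas, "phenotypes": config.phenotypes}
    if config.genotypes:
        inputs["genotypes"] = config.genotypes
    manifest = RunManifest(
        config=asdict(config),
        seed=config.seed,
        input_digests={k: _digest(v) for k, v in inputs.items()},
    )

    betas = preprocess.BetaMatrix.read_tsv(config.betas)
    phenotypes = pd.read_csv(config.phenotypes, sep="\t", index_col=0)
    phenotypes = phenotypes.loc[betas.sample_ids]

    # --- preprocess ---
    betas = preprocess.filter_cpgs(betas, config.max_missing)
    betas = preprocess.impute_missing(betas, config.knn_k)
    known = phenotypes[[config.sex_column]]
    surrogates = preprocess.estimate_surrogates(
        betas, phenotypes[config.protect].to_numpy(float), known, n_sv=config.n_sv
    )
    covariates = pd.concat([known, surrogates], axis=1)
    residuals = preprocess.residualize(betas, covariates)
    residuals.write_tsv(outdir / "residuals.tsv")
    manifest.record(
        "preprocess",
        n_cpgs=residuals.n_cpgs,
        n_surrogates=surrogates.shape[1],
        adjusted_for=list(residuals.adjusted_for),
        protected=config.protect,
    )

    # --- decompose ---
    model = decompose.decompose(
        residuals,
        k=config.k,
        n_restarts=config.n_restarts,
        dominance_threshold=config.dominance_threshold,
        seed=config.seed,
    )
    pd.DataFrame(model.mixing, index=model.sample_ids, columns=model.component_ids()).to_csv(
        outdir / "weights.tsv", sep="\t", index_label="sample_id", float_format="%.10g"
    )
    pd.DataFrame(model.loadings, index=model.component_ids(), columns=model.cpg_ids).to_csv(
        outdir / "loadings.tsv", sep="\t", index_label="component", float_format="%.10g"
    )
    pd.DataFrame(
        {
            "component": model.component_ids(),
            "stability": model.stability,
            "dominance": model.dominance,
            "retained": model.retained,
        }
    ).to_csv(outdir / "diagnostics.tsv", sep="\t", index=False)
    manifest.record(
        "decompose",
        k=model.k,
        n_restarts=model.n_restarts,
        n_retained=int(model.retained.sum()),
        dominance_threshold=config.dominance_threshold,
    )

    # --- associate retained components with age and thickness ---
    retained = [i for i in range(model.k) if model.retained[i]]
    n_tests = config.n_tests_components or len(retained)
    rows = []
    age_blood = phenotypes[config.age_blood].to_numpy(float)
    age_main = phenotypes[config.age_main].to_numpy(float)
    thickness = phenotypes[config.thickness].to_numpy(float)
    for i in retained:
        w = model.mixing[:, i]
        res_age = associate.correlate(w, age_blood, n_tests=n_tests)
        res_thick = associate.adjusted_correlation(
            w,
            thickness,
            z_x=age_blood,
            z_y=age_main,
            n_tests=n_tests,
            adjusted_for=("age_blood", "age_main"),
        )
        rows.append(
            {
                "component": model.component_ids()[i],
                "r_age": res_age.r,
                "p_age": res_age.p_nominal,
                "p_age_corrected": res_age.p_corrected,
                "r_thickness_age_adj": res_thick.r,
                "p_thickness_age_adj": res_thick.p_nominal,
                "p_thickness_corrected": res_thick.p_corrected,
            }
        )
    assoc_table = pd.DataFrame(rows)
    assoc_table.to_csv(outdir / "associations.tsv", sep="\t", index=False)
    manifest.record("associate", n_tests=n_tests, age_variable_x=config.age_blood, age_variable_y=config.age_main)

    # focal component: retained component most correlated with age
    focal = None
    if len(assoc_table):
        focal_row = assoc_table.iloc[assoc_table["r_age"].abs().argmax()]
        focal = str(focal_row["component"])

    # --- mediation ---
    if config.run_mediation and focal is not None:
        w = model.pattern(focal).weights
        med = mediate.bca_bootstrap(
            age_main, w, thickness, n_boot=config.n_boot, ci_level=config.ci_level, seed=config.seed
        )
        (outdir / "mediation.json").write_text(
            json.dumps(
                {
                    "component": focal,
                    "a": med.a,
                    "b": med.b,
                    "c": med.c,
                    "c_prime": med.c_prime,
                    "indirect": med.indirect,
                    "kappa2": med.kappa2,
                    "ci_indirect": med.ci_indirect,
                    "ci_kappa2": med.ci_kappa2,
                    "significant": med.significant,
                    "p_scan": med.p_scan,
                },
                indent=2,
            )
        )
        manifest.record("mediate", component=focal, n_boot=config.n_boot, x_variable=config.age_main)

    # --- signature ---
    if focal is not None:
        sig = signature.select_cpgs(model, focal, n_sigma=config.n_sigma)
        pd.DataFrame(
            {"cpg_id": sig.cpg_ids, "loading": sig.loadings, "direction": sig.direction}
        ).to_csv(outdir / "signature.tsv", sep="\t", index=False)
        manifest.record("signature", component=focal, n_sigma=config.n_sigma, n_cpgs=len(sig))

    # --- CpG-signature gene-set enrichment (needs annotation + GMT) ---
    if focal is not None and config.cpg_annotation and config.transcripts and config.gene_sets:
        from . import enrichment

        cpg_ann = pd.read_csv(config.cpg_annotation, sep="\t")
        tx = pd.read_csv(config.transcripts, sep="\t")
        sets = enrichment.read_gmt(config.gene_sets)
        bias = enrichment.map_cpgs_to_genes(cpg_ann, tx)
        bias = bias[bias >= 1]
        sig = signature.select_cpgs(model, focal, n_sigma=config.n_sigma)
        sig_ann = cpg_ann[cpg_ann["cpg_id"].isin(sig.cpg_ids)]
        sig_counts = enrichment.map_cpgs_to_genes(sig_ann, tx)
        selected = set(sig_counts[sig_counts >= 1].index) & set(bias.index)
        if selected:
            results = enrichment.goseq_wallenius(selected, bias, sets)
            pd.DataFrame(
                [
                    {
                        "set_id": r.set_id,
                        "n_genes": r.n_genes_in_set,
                        "overlap": r.statistic,
                        "p": r.p,
                        "fdr": r.fdr,
                    }
                    for r in results
                ]
            ).to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
            manifest.record("enrichment", n_sets=len(results), n_selected_genes=len(selected))

    # --- regional EFA ---
    region_cols = [c for c in phenotypes.columns if c.startswith(config.region_prefix)]
    if config.run_efa and region_cols:
        regions = phenotypes[region_cols]
        reg_resid = np.column_stack(
            [
                associate.partial_out(
                    regions[c].to_numpy(float),
                    phenotypes[[config.sex_column, config.age_main]],
                )
                for c in region_cols
            ]
        )
        n_factors = efa.parallel_analysis(reg_resid, n_iter=200, seed=config.seed)
        n_factors = max(n_factors, 1)
        factor_model = efa.fit_efa(pd.DataFrame(reg_resid, columns=region_cols), n_factors)
        scores = efa.factor_scores(factor_model, reg_resid)
        pd.DataFrame(
            factor_model.loadings,
            index=region_cols,
            columns=[f"F{j + 1}" for j in range(n_factors)],
        ).to_csv(outdir / "efa_loadings.tsv", sep="\t", index_label="region")
        n_tests_f = config.n_tests_factors or n_factors
        factor_rows = []
        if focal is not None:
            w = model.pattern(focal).weights
            w_adj = associate.partial_out(w, age_blood)
            for j in range(n_factors):
                res = associate.correlate(w_adj, scores[:, j], n_tests=n_tests_f)
                factor_rows.append(
                    {
                        "factor": f"F{j + 1}",
                        "r": res.r,
                        "p": res.p_nominal,
                        "p_corrected": res.p_corrected,
                    }
                )
            pd.DataFrame(factor_rows).to_csv(outdir / "efa_associations.tsv", sep="\t", index=False)
        manifest.record("regional_efa", n_factors=n_factors, n_tests=n_tests_f)

    # --- genetic score ---
    if config.genotypes and focal is not None:
        geno = genescore.GenotypeMatrix.read_tsv(config.genotypes)
        if config.snps:
            snp_table = pd.read_csv(config.snps, sep="\t")
            geno.gene_map = dict(zip(snp_table["snp_id"].astype(str), snp_table["gene"].astype(str)))
        geno = genescore.qc_snps(geno)
        w = model.pattern(focal).weights
        w_adj = associate.partial_out(w, age_blood)
        score = genescore.build_score(geno, w_adj)
        pd.DataFrame(
            {"sample_id": score.sample_ids, "score": score.per_sample_score}
        ).to_csv(outdir / "genetic_score.tsv", sep="\t", index=False)
        res = genescore.score_phenotype_test(
            score, phenotypes[config.memory].to_numpy(float), sidedness="less"
        )
        manifest.record(
            "genescore",
            n_snps=len(score.snps),
            r_memory=res.r,
            p_memory=res.p_nominal,
            stouffer_weighting=config.stouffer_weighting,
        )

    manifest.write_json(outdir / "manifest.json")
    return manifest


def simulate_and_run(design: synthetic.SyntheticDesign, outdir) -> RunManifest:
    """Generate a synthetic fixture set, then run the pipeline on it."""
    outdir = Path(outdir)
    data_dir = outdir / "data"
    paths = synthetic.simulate(design, data_dir)
    config = PipelineConfig(
        betas=str(paths["betas"]),
        phenotypes=str(paths["phenotypes"]),
        genotypes=str(paths["genotypes"]),
        snps=str(paths["snps"]),
        cpg_annotation=str(paths["cpg_annotation"]),
        transcripts=str(paths["transcripts"]),
        gene_sets=str(paths["gene_sets"]),
        seed=design.seed,
        n_restarts=10,
        n_boot=2000,
    )
    return run_pipeline(config, outdir / "run")
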