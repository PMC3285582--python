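"""Configuration and end-to-end orchestration.

``run_pipeline`` executes: simulate -> preprocess/DE -> per-tissue network ->
consensus/preservation -> eigengene-trait association -> twin variance
decomposition -> cis-eQTL + meta-analysis -> eSNP prioritization, writing each
stage's outputs before the next starts and recording a manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import association, consensus, eqtl, io, network, preprocess, synthetic, twin

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "validate_inputs"]


@dataclass
class PipelineConfig:
    """All thresholds default to the study's values."""

    # stage toggles
    run_simulate: bool = True
    run_de: bool = True
    run_network: bool = True
    run_consensus: bool = True
    run_association: bool = True
    run_varcomp: bool = True
    run_eqtl: bool = True
    run_prioritize: bool = True

    # expression filter
    expression_threshold: float = 4.0
    expression_min_fraction: float = 0.10

    # network
    target_r2: float = 0.8
    min_module_size: int = 30
    cut_height_quantile: float = 0.7
    max_power: int = 20

    # significance levels
    de_fdr: float = 0.01
    enrich_fdr: float = 0.01
    mm_p: float = 0.01
    module_qtl_fdr: float = 0.05
    bonferroni_alpha: float = 0.05

    # eQTL
    cis_window: int = 500_000
    qc_maf_lo: float = 0.01
    qc_callrate_a: float = 0.95
    qc_maf_mid: float = 0.05
    qc_callrate_b: float = 0.99
    qc_hwe_p: float = 1e-4

    # simulation scale
    sim_n_samples: int = 100
    sim_n_genes: int = 1000
    sim_module_sizes: list = field(default_factory=lambda: [120, 100, 80, 60, 40])
    sim_n_snps: int = 5000
    sim_twin_probesets: int = 50
    seed: int = 0

    # paths
    out_dir: str = "adiponet_run"

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def validate_inputs(
    expr: pd.DataFrame | None = None,
    annotation: pd.DataFrame | None = None,
    geno: pd.DataFrame | None = None,
    snp_annot: pd.DataFrame | None = None,
    gene_annot: pd.DataFrame | None = None,
) -> list[str]:
    """Cross-consistency checks; returns a list of human-readable issues."""
    issues: list[str] = []
    if expr is not None:
        if expr.index.duplicated().any():
            dupes = expr.index[expr.index.duplicated()].unique().tolist()
            issues.append(f"duplicated probeset ids: {dupes[:5]}")
        if not np.isfinite(expr.to_numpy(float)).all():
            issues.append("non-finite expression values")
    if expr is not None and annotation is not None:
        annotated = set(annotation["sample_id"])
        for s in expr.columns:
            if s not in annotated:
                issues.append(f"expression sample {s!r} missing from annotation")
    if geno is not None:
        miss = geno.isna().mean(axis=1)
        bad = miss[miss > 0.5]
        for snp in bad.index[:10]:
            issues.append(f"SNP {snp!r} has >50% missing calls")
        if snp_annot is not None:
            known = set(snp_annot["snp_id"])
            for snp in geno.index:
                if snp not in known:
                    issues.append(f"genotyped SNP {snp!r} missing coordinates")
    if gene_annot is not None and expr is not None:
        known = set(gene_annot["probeset_id"])
        n_unmapped = sum(1 for p in expr.index if p not in known)
        if n_unmapped:
            issues.append(f"{n_unmapped} probesets lack genomic coordinates")
    return issues


def _stage(manifest, name, t0, **counts):
    manifest["stages"][name] = {"seconds": round(time.time() - t0, 3), **counts}


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full synthetic-data pipeline; returns the manifest dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config_hash": config.config_hash(), "stages": {}}
    rng_seed = config.seed

    expr1 = expr2 = truth = latents = annot = None

    if config.run_simulate:
        t0 = time.time()
        spec = synthetic.CoexpressionSimSpec(
            n_samples=config.sim_n_samples,
            n_genes=config.sim_n_genes,
            module_sizes=list(config.sim_module_sizes),
            seed=rng_seed,
        )
        expr1, expr2, truth, latents = synthetic.simulate_two_tissue_expression(spec)
        annot = synthetic.simulate_traits(
            latents["tissue1"],
            binary_effects={"M1": 1.5},
            quant_effects={"waist": {"M1": 1.0}, "hdl": {"M2": -0.8}},
            seed=rng_seed + 1,
        )
        io.write_expression_tsv(expr1, out / "expression_tissue1.tsv")
        io.write_expression_tsv(expr2, out / "expression_tissue2.tsv")
        io.write_table_tsv(annot, out / "sample_annotation.tsv")
        io.write_json(
            {"true_modules": truth, "seed": rng_seed}, out / "truth.json"
        )
        _stage(manifest, "simulate", t0, genes=len(expr1), samples=expr1.shape[1])

    if expr1 is None:
        manifest["status"] = "no input"
        io.write_json(manifest, out / "manifest.json")
        return manifest

    retained = None
    de = None
    if config.run_de:
        t0 = time.time()
        retained1 = preprocess.filter_expressed(
            expr1, config.expression_threshold, config.expression_min_fraction
        )
        retained2 = preprocess.filter_expressed(
            expr2, config.expression_threshold, config.expression_min_fraction
        )
        retained = retained1.intersection(retained2)
        summary = preprocess.overlap_summary(set(retained1), set(retained2))
        de = preprocess.de_single_gene(
            expr1.loc[retained], annot, "case_status", covariates=("gender", "plate")
        )
        io.write_table_tsv(de, out / "de_results.tsv")
        io.write_json(dataclasses.asdict(summary), out / "expressed_overlap.json")
        _stage(manifest, "de", t0, retained=len(retained), de_hits=int((de["fdr_q"] < config.de_fdr).sum()))

    genes_used = retained if retained is not None else expr1.index
    labels1 = labels2 = eig1 = eig2 = None
    if config.run_network:
        t0 = time.time()
        nets = {}
        for name, expr in (("tissue1", expr1.loc[genes_used]), ("tissue2", expr2.loc[genes_used])):
            corr = network.correlation_matrix(expr)
            beta = network.pick_soft_power(
                corr, range(1, config.max_power + 1), config.target_r2
            )
            tom = network.topological_overlap(network.adjacency(corr, beta))
            labels = network.detect_modules(
                tom, config.min_module_size, config.cut_height_quantile
            )
            eig = network.module_eigengene(expr, labels)
            mm, mm_p = network.module_membership(expr, eig)
            nets[name] = {"tom": tom, "labels": labels, "eig": eig, "beta": beta}
            labels.to_frame().to_csv(out / f"modules_{name}.tsv", sep="\t")
            eig.to_csv(out / f"eigengenes_{name}.tsv", sep="\t")
        labels1, labels2 = nets["tissue1"]["labels"], nets["tissue2"]["labels"]
        eig1, eig2 = nets["tissue1"]["eig"], nets["tissue2"]["eig"]
        manifest["soft_powers"] = {k: nets[k]["beta"] for k in nets}
        _stage(
            manifest, "network", t0,
            modules_t1=int((labels1 != "grey").sum() and labels1[labels1 != "grey"].nunique()),
            modules_t2=int((labels2 != "grey").sum() and labels2[labels2 != "grey"].nunique()),
        )

    cons_labels = None
    if config.run_consensus and labels1 is not None:
        t0 = time.time()
        diss = consensus.consensus_dissimilarity(
            nets["tissue1"]["tom"], nets["tissue2"]["tom"]
        )
        cons_labels = consensus.detect_consensus_modules(
            diss, config.min_module_size, config.cut_height_quantile
        )
        ce1 = network.module_eigengene(expr1.loc[genes_used], cons_labels)
        ce2 = network.module_eigengene(expr2.loc[genes_used], cons_labels)
        if ce1.shape[0] >= 2:
            pres = consensus.preservation(
                consensus.eigengene_network(ce1), consensus.eigengene_network(ce2)
            )
            io.write_json(
                {
                    "density_d": pres.density_d,
                    "per_module_density": pres.per_module_density,
                },
                out / "preservation.json",
            )
            manifest["density_d"] = pres.density_d
        cons_labels.to_frame().to_csv(out / "modules_consensus.tsv", sep="\t")
        _stage(manifest, "consensus", t0, modules=int(cons_labels[cons_labels != "grey"].nunique()))

    if config.run_association and eig1 is not None:
        t0 = time.time()
        assoc = association.eigengene_trait_association(
            eig1, annot, ["case_status", "waist", "hdl"], q_threshold=config.de_fdr
        )
        io.write_table_tsv(assoc, out / "module_trait_association.tsv")
        _stage(manifest, "association", t0, tests=len(assoc), hits=int(assoc["significant"].sum()))

    if config.run_varcomp:
        t0 = time.time()
        tspec = synthetic.TwinSimSpec(n_probesets=config.sim_twin_probesets, seed=rng_seed + 2)
        twin_expr, twin_design = synthetic.simulate_twin_expression(tspec)
        results = []
        for ps in twin_expr.index:
            vc = twin.fit_twin_model(
                twin_expr.loc[ps].to_numpy(), twin_design, n_starts=2, n_polish=1
            )
            results.append(
                {
                    "probeset_id": ps,
                    **vc.as_dict(),
                    "familiality": twin.familiality(vc),
                    "heritability": twin.heritability(vc),
                }
            )
        vc_table = pd.DataFrame(results)
        io.write_table_tsv(vc_table, out / "twin_variance_components.tsv")
        _stage(
            manifest, "varcomp", t0,
            probesets=len(vc_table),
            median_familiality=float(vc_table["familiality"].median()),
        )

    eqtl_meta = None
    if config.run_eqtl:
        t0 = time.time()
        gspec = synthetic.GenotypeSimSpec(
            n_snps=config.sim_n_snps,
            n_samples=expr1.shape[1],
            planted_effects=[
                synthetic.PlantedEffect(0, str(expr1.index[0]), 0.8),
                synthetic.PlantedEffect(1, str(expr1.index[1]), 0.6),
            ],
            seed=rng_seed + 3,
        )
        geno, snp_annot, gene_annot, expr_q = synthetic.simulate_genotypes(gspec, expr1)
        geno_f, qc_report = eqtl.genotype_qc(
            geno,
            maf_lo=config.qc_maf_lo,
            callrate_a=config.qc_callrate_a,
            maf_mid=config.qc_maf_mid,
            callrate_b=config.qc_callrate_b,
            hwe_p=config.qc_hwe_p,
        )
        pairs = eqtl.define_cis_pairs(snp_annot, gene_annot, config.cis_window)
        pairs = pairs[pairs["snp_id"].isin(geno_f.index)]
        study = eqtl.eqtl_single_study(expr_q, geno_f, annot, pairs)
        eqtl_meta = eqtl.meta_fixed_effects([study])
        io.write_table_tsv(qc_report, out / "genotype_qc.tsv")
        io.write_table_tsv(eqtl_meta, out / "eqtl_meta.tsv")
        io.write_dosage_tsv(geno, out / "genotypes.tsv")
        io.write_table_tsv(snp_annot, out / "snp_annotation.tsv")
        _stage(
            manifest, "eqtl", t0,
            pairs=len(study),
            hits=int((eqtl_meta["fdr_q"] < config.de_fdr).sum()),
        )

    if config.run_prioritize and eqtl_meta is not None and de is not None and cons_labels is not None:
        t0 = time.time()
        mm, mm_p = network.module_membership(expr1.loc[genes_used], eig1)
        focus = eig1.index[0] if len(eig1.index) else None
        mm_rows = []
        for g in mm_p.index:
            if focus is not None:
                mm_rows.append(
                    {
                        "probeset_id": g,
                        "tissue": "tissue1",
                        "module": labels1.get(g, "grey"),
                        "mm_p_value": mm_p.loc[g, focus] if focus in mm_p.columns else 1.0,
                    }
                )
        inter = de.copy()  # synthetic single-cohort stand-in for inter-depot DE
        panel = association.prioritize_esnps(
            de,
            pd.DataFrame(mm_rows),
            inter,
            eqtl_meta.rename(columns={"p": "p"}),
            cons_labels,
            focus_modules={"tissue1": focus},
            consensus_module=cons_labels[cons_labels != "grey"].mode().iat[0]
            if (cons_labels != "grey").any()
            else "turquoise",
            de_q=config.de_fdr,
            mm_p=config.mm_p,
            interdepot_q=config.de_fdr,
        )
        io.write_table_tsv(panel, out / "esnp_panel.tsv")
        _stage(manifest, "prioritize", t0, panel=len(panel))

    manifest["status"] = "ok"
    io.write_json(manifest, out / "manifest.json")
    return manifest
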