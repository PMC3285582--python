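"""Synthetic data generators with the statistical structure the pipeline assumes.

All randomness flows through ``numpy.random.default_rng(seed)`` (PCG64), so a
fixed seed yields byte-identical output across runs and platforms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CoexpressionSimSpec",
    "TwinSimSpec",
    "GenotypeSimSpec",
    "PlantedEffect",
    "simulate_two_tissue_expression",
    "simulate_traits",
    "simulate_twin_expression",
    "simulate_genotypes",
]


@dataclass
class CoexpressionSimSpec:
    """Two-tissue rank-1 factor-model expression simulation.

    Each module has one standard-normal latent factor per tissue; the tissue-2
    factor correlates with the tissue-1 factor at
    ``inter_tissue_eigengene_cor``. A gene g in module m is
    w_g * F_m + sqrt(1 - w_g^2) * noise with w_g drawn uniformly from
    ``membership_range``; remaining (background) genes are pure noise. Output
    is shifted/scaled to resemble log2 intensities.
    """

    n_samples: int
    n_genes: int
    module_sizes: list
    membership_range: tuple = (0.5, 0.9)
    inter_tissue_eigengene_cor: float = 0.8
    trait_effects: dict = field(default_factory=dict)
    location: float = 7.0
    scale: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.n_samples < 2 or self.n_genes < 1:
            raise ValueError("invalid dimensions")
        if sum(self.module_sizes) > self.n_genes:
            raise ValueError("modules larger than n_genes")
        lo, hi = self.membership_range
        if not (0 <= lo <= hi <= 1):
            raise ValueError("membership_range must lie in [0, 1]")
        if not -1 <= self.inter_tissue_eigengene_cor <= 1:
            raise ValueError("inter_tissue_eigengene_cor must lie in [-1, 1]")
        vals = [self.n_samples, self.n_genes, lo, hi, self.inter_tissue_eigengene_cor,
                self.location, self.scale, *self.module_sizes]
        if not all(math.isfinite(v) for v in vals):
            raise ValueError("non-finite spec values")
        for m in self.trait_effects:
            if not 0 <= m < len(self.module_sizes):
                raise ValueError(f"trait effect on nonexistent module {m}")

    @property
    def background_fraction(self) -> float:
        return 1.0 - sum(self.module_sizes) / self.n_genes


def simulate_two_tissue_expression(spec: CoexpressionSimSpec):
    """Return (expr tissue1, expr tissue2, true labels, true latent factors).

    Expression matrices are probesets x samples; labels map gene -> module
    index (1-based, 0 = background); latents is a dict with per-tissue
    module x sample factor matrices.
    """
    rng = np.random.default_rng(spec.seed)
    n, g = spec.n_samples, spec.n_genes
    m = len(spec.module_sizes)
    rho = spec.inter_tissue_eigengene_cor

    F1 = rng.standard_normal((m, n))
    F2 = rho * F1 + math.sqrt(max(1 - rho**2, 0.0)) * rng.standard_normal((m, n))

    lo, hi = spec.membership_range
    labels = np.zeros(g, dtype=int)
    start = 0
    for i, size in enumerate(spec.module_sizes):
        labels[start : start + size] = i + 1
        start += size

    w = np.zeros(g)
    in_module = labels > 0
    w[in_module] = rng.uniform(lo, hi, in_module.sum())

    def build(F):
        X = np.empty((g, n))
        noise = rng.standard_normal((g, n))
        for idx in range(g):
            if labels[idx] > 0:
                wg = w[idx]
                X[idx] = wg * F[labels[idx] - 1] + math.sqrt(1 - wg**2) * noise[idx]
            else:
                X[idx] = noise[idx]
        return X * spec.scale + spec.location

    X1 = build(F1)
    X2 = build(F2)

    gene_ids = [f"ps{i:05d}" for i in range(g)]
    sample_ids = [f"S{i:03d}" for i in range(n)]
    module_ids = [f"M{i + 1}" for i in range(m)]
    expr1 = pd.DataFrame(X1, index=gene_ids, columns=sample_ids)
    expr2 = pd.DataFrame(X2, index=gene_ids, columns=sample_ids)
    truth = pd.Series(labels, index=gene_ids, name="module")
    latents = {
        "tissue1": pd.DataFrame(F1, index=module_ids, columns=sample_ids),
        "tissue2": pd.DataFrame(F2, index=module_ids, columns=sample_ids),
        "membership_w": pd.Series(w, index=gene_ids, name="w"),
    }
    return expr1, expr2, truth, latents


def simulate_traits(
    eigengenes: pd.DataFrame,
    binary_effects: dict | None = None,
    quant_effects: dict | None = None,
    noise_sd: float = 1.0,
    n_plates: int = 2,
    seed: int = 0,
) -> pd.DataFrame:
    """Sample annotation with a logistic case/control status and linear traits.

    ``eigengenes`` is modules x samples (rows indexed by module id).
    ``binary_effects`` maps module id -> log-odds per eigengene SD for the
    case/control status; ``quant_effects`` maps trait name -> {module: beta}.
    Gender and plate columns are included as nuisance covariates.
    """
    rng = np.random.default_rng(seed)
    binary_effects = binary_effects or {}
    quant_effects = quant_effects or {}
    for m in binary_effects:
        if m not in eigengenes.index:
            raise ValueError(f"effect on nonexistent module {m!r}")
    for trait, eff in quant_effects.items():
        for m in eff:
            if m not in eigengenes.index:
                raise ValueError(f"effect on nonexistent module {m!r} for {trait!r}")

    samples = list(eigengenes.columns)
    n = len(samples)
    E = eigengenes.to_numpy(float)
    E = (E - E.mean(axis=1, keepdims=True)) / E.std(axis=1, keepdims=True)
    Es = pd.DataFrame(E, index=eigengenes.index, columns=samples)

    logit = np.zeros(n)
    for m, beta in binary_effects.items():
        logit += beta * Es.loc[m].to_numpy()
    prob = 1.0 / (1.0 + np.exp(-logit))
    status = np.where(rng.uniform(size=n) < prob, "case", "control")

    out = pd.DataFrame(
        {
            "sample_id": samples,
            "subject_id": samples,
            "case_status": status,
            "gender": rng.choice(["F", "M"], size=n),
            "plate": [f"P{i % n_plates + 1}" for i in range(n)],
        }
    )
    for trait, eff in quant_effects.items():
        vals = noise_sd * rng.standard_normal(n)
        for m, beta in eff.items():
            vals = vals + beta * Es.loc[m].to_numpy()
        out[trait] = vals
    return out


@dataclass
class TwinSimSpec:
    """Twin cohort simulation with the six-component covariance structure.

    ``variance_components`` is (A, C, individual environment, common visit,
    individual visit, residual): A is the additive-genetic variance (split as
    A/2 into the pair effect and A/2 into the MZ-extra effect), C the common
    environment. Defaults mirror a two-visit MZ/DZ design with technical
    duplicates on a fraction of samples.
    """

    n_mz_pairs: int = 55
    n_dz_pairs: int = 21
    n_visits_per_pair: int = 2
    replicate_fraction: float = 0.15
    variance_components: tuple = (0.4, 0.1, 0.2, 0.1, 0.1, 0.1)
    n_probesets: int = 100
    location: float = 7.0
    n_plates: int = 2
    seed: int = 0

    def __post_init__(self):
        if any(v < 0 for v in self.variance_components):
            raise ValueError("negative variance component")
        if len(self.variance_components) != 6:
            raise ValueError("need exactly 6 variance components")
        if self.n_visits_per_pair not in (1, 2):
            raise ValueError("n_visits_per_pair must be 1 or 2")
        if not 0 <= self.replicate_fraction <= 1:
            raise ValueError("replicate_fraction must lie in [0, 1]")


def simulate_twin_expression(spec: TwinSimSpec):
    """Return (expression probesets x observations, design table).

    The design has one row per observation (aliquot) with pair_id,
    twin_index, zygosity, visit, aliquot, batch, subject_id and sample_id.
    """
    rng = np.random.default_rng(spec.seed)
    A, C, v_ind, v_cv, v_iv, v_res = spec.variance_components
    s_pair = A / 2.0 + C
    s_zyg = A / 2.0

    rows = []
    n_pairs = spec.n_mz_pairs + spec.n_dz_pairs
    for p in range(n_pairs):
        zyg = "MZ" if p < spec.n_mz_pairs else "DZ"
        for t in (1, 2):
            for v in range(1, spec.n_visits_per_pair + 1):
                rows.append((f"pair{p:03d}", t, zyg, v))
    base = pd.DataFrame(rows, columns=["pair_id", "twin_index", "zygosity", "visit"])
    replicate = rng.uniform(size=len(base)) < spec.replicate_fraction

    obs = []
    for (_, r), rep in zip(base.iterrows(), replicate):
        for aliquot in (1, 2) if rep else (1,):
            obs.append((*r, aliquot))
    design = pd.DataFrame(
        obs, columns=["pair_id", "twin_index", "zygosity", "visit", "aliquot"]
    )
    design["subject_id"] = design["pair_id"] + "_t" + design["twin_index"].astype(str)
    design["sample_id"] = (
        design["subject_id"]
        + "_v"
        + design["visit"].astype(str)
        + "_a"
        + design["aliquot"].astype(str)
    )
    design["batch"] = [f"P{i % spec.n_plates + 1}" for i in range(len(design))]

    # index observations into the random-effect units
    pair_idx = design["pair_id"].astype("category").cat.codes.to_numpy()
    twin_key = design["subject_id"].astype("category").cat.codes.to_numpy()
    # MZ-extra effect: one unit per pair for MZ, one per twin for DZ
    zyg_key = np.where(
        design["zygosity"].to_numpy() == "MZ",
        design["pair_id"].to_numpy(),
        design["subject_id"].to_numpy(),
    )
    zyg_idx = pd.Series(zyg_key).astype("category").cat.codes.to_numpy()
    cv_key = (design["pair_id"] + "_v" + design["visit"].astype(str)).to_numpy()
    cv_idx = pd.Series(cv_key).astype("category").cat.codes.to_numpy()
    iv_key = (design["subject_id"] + "_v" + design["visit"].astype(str)).to_numpy()
    iv_idx = pd.Series(iv_key).astype("category").cat.codes.to_numpy()

    g = spec.n_probesets
    n_obs = len(design)

    def draws(var, idx):
        units = idx.max() + 1
        return math.sqrt(var) * rng.standard_normal((g, units))[:, idx]

    X = (
        spec.location
        + draws(s_pair, pair_idx)
        + draws(s_zyg, zyg_idx)
        + draws(v_ind, twin_key)
        + draws(v_cv, cv_idx)
        + draws(v_iv, iv_idx)
        + math.sqrt(v_res) * rng.standard_normal((g, n_obs))
    )
    expr = pd.DataFrame(
        X,
        index=[f"ps{i:05d}" for i in range(g)],
        columns=design["sample_id"].to_list(),
    )
    return expr, design


@dataclass
class PlantedEffect:
    snp_index: int
    probeset_id: str
    beta: float
    distance_bp: int = 10_000


@dataclass
class GenotypeSimSpec:
    """Genotypes in HWE with optional planted additive cis effects.

    Without an explicit ``genome_layout``, genes are placed on one synthetic
    chromosome 1 Mb apart (10 kb long) and SNPs uniformly at random, except
    planted SNPs, which are placed ``distance_bp`` downstream of their gene.
    """

    n_snps: int
    n_samples: int
    maf_range: tuple = (0.05, 0.5)
    planted_effects: list = field(default_factory=list)
    genome_layout: dict | None = None
    chrom: str = "chr1"
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie in (0, 0.5]")
        for eff in self.planted_effects:
            if not 0 <= eff.snp_index < self.n_snps:
                raise ValueError(f"planted SNP index {eff.snp_index} out of range")


def _default_layout(spec: GenotypeSimSpec, probeset_ids, rng):
    gene_len = 10_000
    spacing = 1_000_000
    genes = pd.DataFrame(
        {
            "probeset_id": list(probeset_ids),
            "chrom": spec.chrom,
            "start": [1 + i * spacing for i in range(len(probeset_ids))],
        }
    )
    genes["stop"] = genes["start"] + gene_len - 1
    span = int(genes["stop"].max() + spacing)
    pos = np.sort(rng.integers(1, span, size=spec.n_snps))
    gene_pos = genes.set_index("probeset_id")
    for eff in spec.planted_effects:
        pos[eff.snp_index] = int(gene_pos.loc[eff.probeset_id, "stop"]) + eff.distance_bp
    return genes, pos


def simulate_genotypes(spec: GenotypeSimSpec, expression: pd.DataFrame):
    """Return (genotypes, SNP annotation, gene annotation, modified expression).

    Dosages are Binomial(2, maf) draws per sample (HWE); planted probesets get
    beta * dosage added to their expression. Planted SNPs sit within the
    declared distance of their gene.
    """
    for eff in spec.planted_effects:
        if eff.probeset_id not in expression.index:
            raise ValueError(f"planted probeset {eff.probeset_id!r} not in expression")
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.maf_range
    mafs = rng.uniform(lo, hi, spec.n_snps)
    samples = list(expression.columns)
    G = rng.binomial(2, mafs[:, None], size=(spec.n_snps, len(samples))).astype(float)
    snp_ids = [f"rs{i:06d}" for i in range(spec.n_snps)]
    geno = pd.DataFrame(G, index=snp_ids, columns=samples)

    if spec.genome_layout is None:
        genes, pos = _default_layout(spec, expression.index, rng)
    else:
        genes = pd.DataFrame(spec.genome_layout["genes"])
        pos = np.asarray(spec.genome_layout["snp_positions"])
        if len(pos) != spec.n_snps:
            raise ValueError("snp_positions length mismatch")
    snp_annot = pd.DataFrame(
        {
            "snp_id": snp_ids,
            "chrom": spec.chrom,
            "pos": pos,
            "ref": "A",
            "alt": "G",
            "maf": mafs,
        }
    )

    expr = expression.copy()
    for eff in spec.planted_effects:
        expr.loc[eff.probeset_id] = (
            expr.loc[eff.probeset_id] + eff.beta * geno.loc[snp_ids[eff.snp_index]]
        )
    return geno, snp_annot, genes, expr
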