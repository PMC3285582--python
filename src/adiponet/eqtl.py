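"""Genotype QC, cis-pair definition, eQTL regression, and meta-analysis.

Genotype matrices are DataFrames (SNP ids x sample ids) of minor-allele
dosages in {0, 1, 2} with NaN for missing calls.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import _design_matrix, bh_fdr
from .twin import fit_twin_model

logger = logging.getLogger(__name__)

__all__ = [
    "hwe_exact_test",
    "genotype_qc",
    "define_cis_pairs",
    "eqtl_single_study",
    "eqtl_twin_study",
    "meta_fixed_effects",
    "empirical_p",
    "module_qtl",
]


def hwe_exact_test(n_hom_major: int, n_het: int, n_hom_minor: int) -> float:
    """Exact Hardy-Weinberg test conditional on the observed allele counts.

    Sums the probabilities of all heterozygote counts (with the same allele
    totals) that are no more likely than the observed one.
    """
    if min(n_hom_major, n_het, n_hom_minor) < 0:
        raise ValueError("negative genotype count")
    n = n_hom_major + n_het + n_hom_minor
    if n == 0:
        return 1.0
    n_minor = n_het + 2 * n_hom_minor
    n_major = n_het + 2 * n_hom_major
    if n_minor > n_major:
        n_minor, n_major = n_major, n_minor
    # P(het = h | allele counts) proportional to n! / (a! h! b!) * 2^h
    # with a, b the implied homozygote counts; computed in log space.
    hets = range(n_minor % 2, n_minor + 1, 2)
    logs = []
    for h in hets:
        a = (n_minor - h) // 2
        b = n - h - a
        lg = (
            math.lgamma(n + 1)
            - math.lgamma(a + 1)
            - math.lgamma(h + 1)
            - math.lgamma(b + 1)
            + h * math.log(2.0)
        )
        logs.append(lg)
    logs = np.array(logs)
    probs = np.exp(logs - logs.max())
    probs /= probs.sum()
    obs = list(hets).index(n_het)
    p = probs[probs <= probs[obs] * (1 + 1e-12)].sum()
    return float(min(p, 1.0))


def _hwe_chi2(n_hom_major: int, n_het: int, n_hom_minor: int) -> float:
    n = n_hom_major + n_het + n_hom_minor
    if n == 0:
        return 1.0
    q = (n_het + 2 * n_hom_minor) / (2 * n)
    exp = np.array([n * (1 - q) ** 2, 2 * n * q * (1 - q), n * q**2])
    obs = np.array([n_hom_major, n_het, n_hom_minor])
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.nansum(np.where(exp > 0, (obs - exp) ** 2 / exp, 0.0))
    return float(stats.chi2.sf(chi2, 1))


def genotype_qc(
    geno: pd.DataFrame,
    unrelated_samples=None,
    maf_lo: float = 0.01,
    callrate_a: float = 0.95,
    maf_mid: float = 0.05,
    callrate_b: float = 0.99,
    hwe_p: float = 1e-4,
    hwe_method: str = "exact",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Filter SNPs on minor allele frequency, call rate, and HWE.

    A SNP is dropped when MAF < ``maf_lo``; when call rate < ``callrate_a``
    and MAF > ``maf_mid``; when call rate < ``callrate_b`` and MAF <=
    ``maf_mid``; or when the HWE test on the unrelated samples gives
    p < ``hwe_p``. Returns (filtered genotypes, per-SNP QC report).
    """
    G = geno.to_numpy(float)
    n_samples = G.shape[1]
    n_called = np.sum(~np.isnan(G), axis=1)
    callrate = n_called / n_samples
    with np.errstate(invalid="ignore"):
        freq = np.nansum(G, axis=1) / (2 * np.maximum(n_called, 1))
    maf = np.minimum(freq, 1 - freq)
    maf[n_called == 0] = 0.0

    if unrelated_samples is None:
        unrel = geno
    else:
        unrel = geno[[s for s in unrelated_samples if s in geno.columns]]
    hwe = np.ones(len(geno))
    if unrel.shape[1] == 0:
        logger.warning("no unrelated samples; HWE filter skipped")
    else:
        U = unrel.to_numpy(float)
        test = hwe_exact_test if hwe_method == "exact" else _hwe_chi2
        for i in range(U.shape[0]):
            row = U[i][~np.isnan(U[i])]
            counts = [(np.rint(row) == g).sum() for g in (0, 1, 2)]
            hwe[i] = test(*counts)

    drop_maf = maf < maf_lo
    drop_cr = ((callrate < callrate_a) & (maf > maf_mid)) | (
        (callrate < callrate_b) & (maf <= maf_mid)
    )
    drop_hwe = hwe < hwe_p
    keep = ~(drop_maf | drop_cr | drop_hwe)
    report = pd.DataFrame(
        {
            "snp_id": geno.index,
            "maf": maf,
            "call_rate": callrate,
            "hwe_p": hwe,
            "fail_maf": drop_maf,
            "fail_callrate": drop_cr,
            "fail_hwe": drop_hwe,
            "kept": keep,
        }
    )
    return geno.loc[keep], report


def define_cis_pairs(
    snps: pd.DataFrame, genes: pd.DataFrame, window: int = 500_000
) -> pd.DataFrame:
    """All (snp, probeset) pairs with the SNP within ``window`` bp of the gene.

    Boundaries are inclusive: start - window <= pos <= stop + window on the
    same chromosome. ``snps`` needs columns (snp_id, chrom, pos); ``genes``
    needs (probeset_id, chrom, start, stop), all positions 1-based.
    """
    if (genes["start"] > genes["stop"]).any():
        raise ValueError("gene start must be <= stop")
    out = []
    for chrom, gsub in genes.groupby("chrom"):
        ssub = snps[snps["chrom"] == chrom]
        if ssub.empty:
            continue
        pos = ssub["pos"].to_numpy()
        for _, g in gsub.iterrows():
            mask = (pos >= g["start"] - window) & (pos <= g["stop"] + window)
            for sid in ssub["snp_id"].to_numpy()[mask]:
                out.append((sid, g["probeset_id"]))
    return pd.DataFrame(out, columns=["snp_id", "probeset_id"])


def _ols_fit(y: np.ndarray, X: np.ndarray):
    n, p = X.shape
    XtX_inv = np.linalg.pinv(X.T @ X)
    beta = XtX_inv @ (X.T @ y)
    resid = y - X @ beta
    df = n - p
    sigma2 = float(resid @ resid) / df
    se = math.sqrt(max(sigma2 * XtX_inv[1, 1], 0.0))
    if se == 0:
        pval = 1.0 if beta[1] == 0 else 0.0
    else:
        pval = 2.0 * stats.t.sf(abs(beta[1] / se), df)
    return float(beta[1]), se, float(pval)


def eqtl_single_study(
    expr: pd.DataFrame,
    geno: pd.DataFrame,
    annotation: pd.DataFrame,
    pairs: pd.DataFrame,
    covariates=("gender", "plate"),
    min_obs: int = 10,
) -> pd.DataFrame:
    """Additive-model OLS of expression on minor-allele dosage per cis pair.

    Missing dosages are dropped pairwise (complete cases per pair); pairs with
    fewer than ``min_obs`` complete observations are skipped with a log entry.
    """
    samples = [s for s in expr.columns if s in geno.columns]
    annot = annotation.set_index("sample_id").loc[samples]
    covs = [c for c in covariates if c in annot.columns and annot[c].nunique() > 1]
    blocks = [np.ones((len(samples), 1))]
    for c in covs:
        blocks.append(pd.get_dummies(annot[c], drop_first=True).to_numpy(float))
    C = np.hstack(blocks)  # intercept + covariates, no dosage yet
    E = expr[samples]
    G = geno[samples]
    rows = []
    for snp, ps in pairs[["snp_id", "probeset_id"]].itertuples(index=False):
        if snp not in G.index or ps not in E.index:
            continue
        g = G.loc[snp].to_numpy(float)
        y = E.loc[ps].to_numpy(float)
        ok = ~np.isnan(g) & ~np.isnan(y)
        if ok.sum() < min_obs:
            logger.info("pair (%s, %s): %d complete obs; skipped", snp, ps, ok.sum())
            continue
        X = np.hstack([C[ok][:, :1], g[ok][:, None], C[ok][:, 1:]])
        if np.nanstd(g[ok]) == 0:
            continue
        beta, se, p = _ols_fit(y[ok], X)
        rows.append((snp, ps, beta, se, p, int(ok.sum())))
    return pd.DataFrame(
        rows, columns=["snp_id", "probeset_id", "beta", "se", "p", "n"]
    )


def eqtl_twin_study(
    expr: pd.DataFrame,
    geno: pd.DataFrame,
    design: pd.DataFrame,
    pairs: pd.DataFrame,
    min_obs: int = 10,
    **fit_kwargs,
) -> pd.DataFrame:
    """Twin mixed-model eQTL: dosage and plate fixed, twin structure random.

    ``design`` rows are observations with a ``sample_id`` column mapping into
    ``expr``'s columns and a ``subject_id`` column mapping into ``geno``'s
    columns (genotypes are per subject; both co-twins of an MZ pair may share
    a genotype column). The Wald test on the dosage coefficient is reported.
    """
    rows = []
    for snp, ps in pairs[["snp_id", "probeset_id"]].itertuples(index=False):
        if snp not in geno.index or ps not in expr.index:
            continue
        subj_col = "subject_id" if "subject_id" in design.columns else "sample_id"
        dose = geno.loc[snp]
        d = design[design[subj_col].isin(dose.index) & design["sample_id"].isin(expr.columns)].copy()
        d["dosage"] = dose.loc[d[subj_col]].to_numpy(float)
        d = d[np.isfinite(d["dosage"])]
        if len(d) < min_obs or d["dosage"].nunique() < 2:
            logger.info("pair (%s, %s): insufficient data; skipped", snp, ps)
            continue
        y = expr.loc[ps, d["sample_id"]].to_numpy(float)
        vc = fit_twin_model(
            y,
            d.drop(columns=["dosage"]),
            extra_fixed=d[["dosage"]].reset_index(drop=True),
            **fit_kwargs,
        )
        fe = vc.fixed_effects.set_index("name").loc["dosage"]
        rows.append((snp, ps, fe["beta"], fe["se"], fe["p"], len(d)))
    return pd.DataFrame(
        rows, columns=["snp_id", "probeset_id", "beta", "se", "p", "n"]
    )


def meta_fixed_effects(study_results: list[pd.DataFrame]) -> pd.DataFrame:
    """Inverse-variance fixed-effects meta-analysis across studies.

    Studies are joined on (snp_id, probeset_id). Weights w_i = 1/se_i^2;
    beta_meta = sum(w b)/sum(w); se_meta = 1/sqrt(sum w); z = beta/se with a
    two-sided normal p; Cochran's Q with k - 1 df measures heterogeneity.
    Pairs present in a single study carry that study's estimate with Q
    undefined. BH FDR is computed across all pairs.
    """
    if not study_results:
        raise ValueError("no studies supplied")
    frames = []
    for i, df in enumerate(study_results):
        bad = df["se"] <= 0
        if bad.any():
            logger.warning("study %d: %d records with se <= 0 excluded", i, int(bad.sum()))
            df = df[~bad]
        frames.append(df.assign(study=i))
    stacked = pd.concat(frames, ignore_index=True)
    rows = []
    for (snp, ps), grp in stacked.groupby(["snp_id", "probeset_id"], sort=True):
        b = grp["beta"].to_numpy(float)
        se = grp["se"].to_numpy(float)
        w = 1.0 / se**2
        beta = float((w * b).sum() / w.sum())
        se_meta = float(1.0 / math.sqrt(w.sum()))
        z = beta / se_meta
        p = 2.0 * stats.norm.sf(abs(z))
        k = len(grp)
        if k > 1:
            q = float((w * (b - beta) ** 2).sum())
            het_p = float(stats.chi2.sf(q, k - 1))
        else:
            q, het_p = np.nan, np.nan
        rows.append((snp, ps, beta, se_meta, z, p, k, q, het_p))
    out = pd.DataFrame(
        rows,
        columns=[
            "snp_id", "probeset_id", "beta_meta", "se_meta", "z", "p",
            "n_studies", "het_q", "het_p",
        ],
    )
    out["het_flag"] = out["het_p"] < 0.05
    out["fdr_q"] = bh_fdr(out["p"].to_numpy())
    return out


def empirical_p(
    y,
    cis_geno: pd.DataFrame,
    annotation: pd.DataFrame | None = None,
    covariates=(),
    B: int = 1000,
    seed: int = 0,
) -> tuple[float, float]:
    """Permutation-based empirical p for a gene's best cis SNP.

    Expression values are permuted across samples ``B`` times; the empirical p
    is (1 + #{permutations whose min cis p <= observed min p}) / (B + 1).
    Returns (empirical p, observed min nominal p).
    """
    if cis_geno.shape[0] == 0:
        raise ValueError("no cis SNPs")
    if B < 100:
        logger.warning("B = %d is small; empirical p resolution is coarse", B)
    samples = list(cis_geno.columns)
    yv = np.asarray(
        y.loc[samples] if isinstance(y, pd.Series) else y, float
    )
    n = len(samples)
    blocks = [np.ones((n, 1))]
    if annotation is not None and covariates:
        annot = annotation.set_index("sample_id").loc[samples]
        for c in covariates:
            if c in annot.columns and annot[c].nunique() > 1:
                blocks.append(pd.get_dummies(annot[c], drop_first=True).to_numpy(float))
    C = np.hstack(blocks)
    G = cis_geno.to_numpy(float)

    def min_p(yy):
        best = 1.0
        for g in G:
            ok = ~np.isnan(g)
            if ok.sum() < 3 or np.std(g[ok]) == 0:
                continue
            X = np.hstack([C[ok][:, :1], g[ok][:, None], C[ok][:, 1:]])
            _, _, p = _ols_fit(yy[ok], X)
            best = min(best, p)
        return best

    obs = min_p(yv)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(B):
        hits += min_p(rng.permutation(yv)) <= obs
    return (1.0 + hits) / (B + 1.0), obs


def module_qtl(
    eigengene: pd.Series,
    geno: pd.DataFrame,
    annotation: pd.DataFrame | None = None,
    covariates=(),
    fdr_level: float = 0.05,
    min_obs: int = 10,
) -> pd.DataFrame:
    """Genome-wide association of a module eigengene with every SNP."""
    samples = [s for s in eigengene.index if s in geno.columns]
    yfull = eigengene.loc[samples].to_numpy(float)
    blocks = [np.ones((len(samples), 1))]
    if annotation is not None and covariates:
        annot = annotation.set_index("sample_id").loc[samples]
        for c in covariates:
            if c in annot.columns and annot[c].nunique() > 1:
                blocks.append(pd.get_dummies(annot[c], drop_first=True).to_numpy(float))
    C = np.hstack(blocks)
    G = geno[samples]
    rows = []
    for snp in G.index:
        g = G.loc[snp].to_numpy(float)
        ok = ~np.isnan(g)
        if ok.sum() < min_obs or np.std(g[ok]) == 0:
            continue
        X = np.hstack([C[ok][:, :1], g[ok][:, None], C[ok][:, 1:]])
        beta, se, p = _ols_fit(yfull[ok], X)
        rows.append((snp, beta, se, p, int(ok.sum())))
    out = pd.DataFrame(rows, columns=["snp_id", "beta", "se", "p", "n"])
    out["fdr_q"] = bh_fdr(out["p"].to_numpy())
    out["significant"] = out["fdr_q"] < fdr_level
    return out
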