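from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from adiponet import eqtl, synthetic


def hwe_oracle(n_aa, n_ab, n_bb):
    """Exact HWE p by direct rational enumeration over heterozygote counts."""
    n = n_aa + n_ab + n_bb
    nb = n_ab + 2 * n_bb
    na = 2 * n - nb
    if nb > na:
        na, nb = nb, na
    probs = {}
    denom = comb(2 * n, nb)
    for h in range(nb % 2, nb + 1, 2):
        bb = (nb - h) // 2
        aa = n - h - bb
        probs[h] = Fraction(comb(n, bb) * comb(n - bb, h) * 2**h, denom)
    p_obs = probs[n_ab]
    return float(sum(p for p in probs.values() if p <= p_obs))


class TestHweExactTest:
    @pytest.mark.parametrize(
        "counts",
        [(20, 60, 20), (50, 30, 20), (5, 5, 5), (0, 10, 0), (10, 0, 10), (3, 7, 0)],
    )
    def test_matches_enumeration_oracle(self, counts):
        assert eqtl.hwe_exact_test(*counts) == pytest.approx(
            hwe_oracle(*counts), abs=1e-12
        )

    def test_close_to_chi2_at_large_n_in_hwe(self):
        # n = 10,000 at exact HWE proportions, q = 0.3
        n = 10_000
        q = 0.3
        aa = round(n * (1 - q) ** 2)
        ab = round(2 * n * q * (1 - q))
        bb = n - aa - ab
        p_exact = eqtl.hwe_exact_test(aa, ab, bb)
        p_chi2 = eqtl._hwe_chi2(aa, ab, bb)
        assert abs(p_exact - p_chi2) < 0.01

    def test_null_uniform_ks(self):
        # exact-test p-values across null SNPs are (super)uniform
        gen = np.random.default_rng(0)
        ps = []
        for _ in range(1000):
            maf = gen.uniform(0.1, 0.5)
            g = gen.binomial(2, maf, size=200)
            ps.append(eqtl.hwe_exact_test((g == 0).sum(), (g == 1).sum(), (g == 2).sum()))
        # discrete conservative test: check no excess of small p-values
        assert np.mean(np.array(ps) < 0.05) <= 0.06

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            eqtl.hwe_exact_test(-1, 0, 0)


class TestGenotypeQc:
    def _geno(self, rows, samples=None):
        arr = np.asarray(rows, float)
        samples = samples or [f"s{i}" for i in range(arr.shape[1])]
        return pd.DataFrame(arr, index=[f"rs{i}" for i in range(arr.shape[0])], columns=samples)

    def test_monomorphic_dropped(self):
        geno = self._geno([np.zeros(100), np.random.default_rng(1).binomial(2, 0.3, 100)])
        kept, report = eqtl.genotype_qc(geno)
        assert "rs0" not in kept.index
        assert report.set_index("snp_id").loc["rs0", "fail_maf"]

    def test_low_maf_needs_high_callrate(self):
        gen = np.random.default_rng(2)
        g = gen.binomial(2, 0.04, size=100).astype(float)
        g[:2] = np.nan  # call rate 0.98 < 0.99 with MAF <= 0.05
        geno = self._geno([g])
        kept, report = eqtl.genotype_qc(geno, hwe_p=0.0)
        assert len(kept) == 0
        assert report["fail_callrate"].iloc[0]

    def test_common_maf_tolerates_lower_callrate(self):
        gen = np.random.default_rng(3)
        g = gen.binomial(2, 0.4, size=100).astype(float)
        g[:2] = np.nan  # call rate 0.98 >= 0.95 with MAF > 0.05
        geno = self._geno([g])
        kept, _ = eqtl.genotype_qc(geno, hwe_p=0.0)
        assert len(kept) == 1

    def test_hwe_failure_dropped(self):
        # all heterozygotes: extreme HWE violation
        geno = self._geno([np.ones(200)])
        kept, report = eqtl.genotype_qc(geno)
        assert len(kept) == 0
        assert report["fail_hwe"].iloc[0]

    def test_sample_order_invariance(self):
        gen = np.random.default_rng(4)
        geno = self._geno(gen.binomial(2, 0.3, size=(20, 80)).astype(float))
        kept1, _ = eqtl.genotype_qc(geno)
        perm = gen.permutation(geno.columns)
        kept2, _ = eqtl.genotype_qc(geno[perm])
        assert list(kept1.index) == list(kept2.index)

    def test_unrelated_subset_used_for_hwe(self):
        # HWE-violating pattern only among related duplicates
        gen = np.random.default_rng(5)
        base = gen.binomial(2, 0.3, size=50).astype(float)
        geno = self._geno([np.concatenate([base, np.ones(50)])])
        unrelated = [f"s{i}" for i in range(50)]
        kept, _ = eqtl.genotype_qc(geno, unrelated_samples=unrelated)
        assert len(kept) == 1


class TestDefineCisPairs:
    def _layout(self):
        genes = pd.DataFrame(
            {
                "probeset_id": ["g1", "g2"],
                "chrom": ["chr1", "chr1"],
                "start": [1_000_000, 5_000_000],
                "stop": [1_010_000, 5_020_000],
            }
        )
        return genes

    def test_boundary_inclusive(self):
        genes = self._layout()
        snps = pd.DataFrame(
            {
                "snp_id": ["a", "b", "c"],
                "chrom": "chr1",
                "pos": [500_000, 1_510_000, 1_510_001],
            }
        )
        pairs = eqtl.define_cis_pairs(snps, genes)
        got = set(map(tuple, pairs.to_numpy()))
        assert ("a", "g1") in got  # pos == start - window
        assert ("b", "g1") in got  # pos == stop + window
        assert ("c", "g1") not in got  # one bp beyond

    def test_chromosome_mismatch_excluded(self):
        genes = self._layout()
        snps = pd.DataFrame({"snp_id": ["a"], "chrom": ["chr2"], "pos": [1_000_000]})
        assert len(eqtl.define_cis_pairs(snps, genes)) == 0

    def test_matches_brute_force(self):
        gen = np.random.default_rng(6)
        for _ in range(20):
            genes = pd.DataFrame(
                {
                    "probeset_id": [f"g{i}" for i in range(10)],
                    "chrom": gen.choice(["chr1", "chr2"], 10),
                    "start": gen.integers(1, 10_000_000, 10),
                }
            )
            genes["stop"] = genes["start"] + gen.integers(1000, 100_000, 10)
            snps = pd.DataFrame(
                {
                    "snp_id": [f"rs{i}" for i in range(100)],
                    "chrom": gen.choice(["chr1", "chr2"], 100),
                    "pos": gen.integers(1, 10_000_000, 100),
                }
            )
            got = set(map(tuple, eqtl.define_cis_pairs(snps, genes, 500_000).to_numpy()))
            expect = set()
            for _, s in snps.iterrows():
                for _, g in genes.iterrows():
                    if s["chrom"] == g["chrom"] and g["start"] - 500_000 <= s["pos"] <= g["stop"] + 500_000:
                        expect.add((s["snp_id"], g["probeset_id"]))
            assert got == expect


def _study_fixture(seed=0, n=150, beta=0.0, maf=0.3, n_null=10):
    gen = np.random.default_rng(seed)
    samples = [f"s{i}" for i in range(n)]
    g = gen.binomial(2, maf, size=n).astype(float)
    rows = {"ps_target": beta * g + gen.normal(size=n)}
    geno_rows = {"rs_target": g}
    for i in range(n_null):
        rows[f"ps_null{i}"] = gen.normal(size=n)
        geno_rows[f"rs_null{i}"] = gen.binomial(2, maf, size=n).astype(float)
    expr = pd.DataFrame(rows, index=samples).T
    geno = pd.DataFrame(geno_rows, index=samples).T
    annot = pd.DataFrame(
        {
            "sample_id": samples,
            "gender": gen.choice(["F", "M"], n),
            "plate": gen.choice(["P1", "P2"], n),
        }
    )
    pairs = pd.DataFrame(
        {
            "snp_id": ["rs_target"] + [f"rs_null{i}" for i in range(n_null)],
            "probeset_id": ["ps_target"] + [f"ps_null{i}" for i in range(n_null)],
        }
    )
    return expr, geno, annot, pairs


class TestEqtlSingleStudy:
    def test_expression_equals_dosage(self):
        gen = np.random.default_rng(7)
        n = 50
        g = gen.binomial(2, 0.4, n).astype(float)
        expr = pd.DataFrame([g], index=["ps"], columns=[f"s{i}" for i in range(n)])
        geno = pd.DataFrame([g], index=["rs"], columns=expr.columns)
        annot = pd.DataFrame({"sample_id": expr.columns})
        pairs = pd.DataFrame({"snp_id": ["rs"], "probeset_id": ["ps"]})
        res = eqtl.eqtl_single_study(expr, geno, annot, pairs, covariates=())
        assert res["beta"].iloc[0] == pytest.approx(1.0, abs=1e-10)
        assert res["p"].iloc[0] < 1e-30

    def test_null_p_uniform(self):
        gen = np.random.default_rng(8)
        n, m = 100, 500
        samples = [f"s{i}" for i in range(n)]
        expr = pd.DataFrame(gen.normal(size=(m, n)), index=[f"ps{i}" for i in range(m)], columns=samples)
        geno = pd.DataFrame(
            gen.binomial(2, 0.3, size=(m, n)).astype(float),
            index=[f"rs{i}" for i in range(m)], columns=samples,
        )
        annot = pd.DataFrame({"sample_id": samples})
        pairs = pd.DataFrame(
            {"snp_id": [f"rs{i}" for i in range(m)], "probeset_id": [f"ps{i}" for i in range(m)]}
        )
        res = eqtl.eqtl_single_study(expr, geno, annot, pairs, covariates=())
        assert stats.kstest(res["p"], "uniform").pvalue > 0.01

    def test_planted_beta_sampling_distribution(self):
        cover = 0
        n_seeds = 40
        for seed in range(n_seeds):
            expr, geno, annot, pairs = _study_fixture(seed=seed, beta=0.5, n_null=0)
            res = eqtl.eqtl_single_study(expr, geno, annot, pairs)
            cover += abs(res["beta"].iloc[0] - 0.5) < 0.2
        assert cover >= 0.9 * n_seeds

    def test_min_obs_skip(self):
        expr, geno, annot, pairs = _study_fixture(seed=9, n=8, n_null=0)
        res = eqtl.eqtl_single_study(expr, geno, annot, pairs, min_obs=10)
        assert len(res) == 0


class TestEqtlTwinStudy:
    def _twin_fixture(self, beta, seed):
        spec = synthetic.TwinSimSpec(
            n_mz_pairs=30, n_dz_pairs=15, n_visits_per_pair=1,
            replicate_fraction=0.0,
            variance_components=(0.3, 0.1, 0.2, 0.0, 0.0, 0.4),
            n_probesets=1, seed=seed,
        )
        expr, design = synthetic.simulate_twin_expression(spec)
        gen = np.random.default_rng(seed + 1000)
        subjects = design["subject_id"].unique()
        dose = pd.Series(gen.binomial(2, 0.3, len(subjects)).astype(float), index=subjects)
        expr.iloc[0] += beta * dose.loc[design["subject_id"]].to_numpy()
        geno = pd.DataFrame([dose], index=["rs1"])
        pairs = pd.DataFrame({"snp_id": ["rs1"], "probeset_id": [expr.index[0]]})
        return expr, geno, design, pairs

    def test_planted_effect_recovered(self):
        cover = 0
        n_seeds = 15
        for seed in range(n_seeds):
            expr, geno, design, pairs = self._twin_fixture(0.5, seed)
            res = eqtl.eqtl_twin_study(expr, geno, design, pairs, n_starts=2, n_polish=1)
            cover += abs(res["beta"].iloc[0] - 0.5) <= 2 * res["se"].iloc[0]
        assert cover >= 12

    def test_null_type_i_error(self):
        rejections = []
        for seed in range(60):
            expr, geno, design, pairs = self._twin_fixture(0.0, 100 + seed)
            res = eqtl.eqtl_twin_study(expr, geno, design, pairs, n_starts=2, n_polish=1)
            rejections.append(res["p"].iloc[0] < 0.05)
        assert np.mean(rejections) < 0.15

    def test_matches_ols_when_no_random_variance(self):
        expr, geno, design, pairs = self._twin_fixture(0.5, 7)
        res_t = eqtl.eqtl_twin_study(
            expr, geno, design, pairs, n_starts=1, n_polish=1,
            fix_zero=(
                "sigma2_pair", "sigma2_zyg", "sigma2_ind_env",
                "sigma2_common_visit", "sigma2_ind_visit",
            ),
        )
        annot = pd.DataFrame({"sample_id": design["sample_id"]})
        expr_flat = expr.copy()
        geno_flat = pd.DataFrame(
            [geno.loc["rs1", design["subject_id"]].to_numpy()],
            index=["rs1"], columns=design["sample_id"],
        )
        res_o = eqtl.eqtl_single_study(
            expr_flat, geno_flat, annot, pairs, covariates=()
        )
        assert res_t["beta"].iloc[0] == pytest.approx(res_o["beta"].iloc[0], abs=1e-6)


class TestMetaFixedEffects:
    def _df(self, beta, se, snp="rs1", ps="p1"):
        return pd.DataFrame(
            {"snp_id": [snp], "probeset_id": [ps], "beta": [beta], "se": [se],
             "p": [0.5], "n": [100]}
        )

    def test_equal_weight_arithmetic(self):
        res = eqtl.meta_fixed_effects([self._df(1.0, 1.0), self._df(3.0, 1.0)])
        assert res["beta_meta"].iloc[0] == pytest.approx(2.0)
        assert res["se_meta"].iloc[0] == pytest.approx(1 / np.sqrt(2))

    def test_single_study_identity(self):
        res = eqtl.meta_fixed_effects([self._df(0.7, 0.2)])
        assert res["beta_meta"].iloc[0] == pytest.approx(0.7)
        assert res["se_meta"].iloc[0] == pytest.approx(0.2)
        assert np.isnan(res["het_q"].iloc[0])

    def test_k_identical_studies_se_scaling(self):
        for k in (2, 3, 5):
            res = eqtl.meta_fixed_effects([self._df(1.0, 0.4)] * k)
            assert res["se_meta"].iloc[0] == pytest.approx(0.4 / np.sqrt(k))

    def test_split_halves_close_to_pooled(self):
        gen = np.random.default_rng(10)
        n = 300
        g = gen.binomial(2, 0.3, n).astype(float)
        y = 0.4 * g + gen.normal(size=n)
        halves = []
        for sl in (slice(0, 150), slice(150, 300)):
            samples = [f"s{i}" for i in range(n)][sl]
            expr = pd.DataFrame([y[sl]], index=["p1"], columns=samples)
            geno = pd.DataFrame([g[sl]], index=["rs1"], columns=samples)
            annot = pd.DataFrame({"sample_id": samples})
            halves.append(
                eqtl.eqtl_single_study(
                    expr, geno, annot,
                    pd.DataFrame({"snp_id": ["rs1"], "probeset_id": ["p1"]}),
                    covariates=(),
                )
            )
        meta = eqtl.meta_fixed_effects(halves)
        from adiponet.eqtl import _ols_fit

        X = np.column_stack([np.ones(n), g])
        beta_full, se_full, _ = _ols_fit(y, X)
        assert abs(meta["beta_meta"].iloc[0] - beta_full) <= 2 * se_full

    def test_nonpositive_se_excluded(self):
        res = eqtl.meta_fixed_effects([self._df(1.0, 0.0), self._df(2.0, 1.0)])
        assert res["beta_meta"].iloc[0] == pytest.approx(2.0)

    def test_heterogeneity_flag(self):
        res = eqtl.meta_fixed_effects([self._df(0.0, 0.1), self._df(5.0, 0.1)])
        assert res["het_p"].iloc[0] < 0.05
        assert bool(res["het_flag"].iloc[0])


class TestEmpiricalP:
    def test_strong_eqtl_minimum_p(self):
        gen = np.random.default_rng(11)
        n = 80
        g = gen.binomial(2, 0.4, n).astype(float)
        y = pd.Series(g * 3.0 + 0.01 * gen.normal(size=n),
                      index=[f"s{i}" for i in range(n)])
        cis = pd.DataFrame(
            [g] + [gen.binomial(2, 0.3, n).astype(float) for _ in range(4)],
            columns=y.index,
        )
        p, _ = eqtl.empirical_p(y, cis, B=199, seed=5)
        assert p == pytest.approx(1 / 200)

    def test_null_gene_p_not_extreme(self):
        gen = np.random.default_rng(12)
        n = 60
        y = pd.Series(gen.normal(size=n), index=[f"s{i}" for i in range(n)])
        cis = pd.DataFrame(
            [gen.binomial(2, 0.3, n).astype(float) for _ in range(3)], columns=y.index
        )
        ps = [eqtl.empirical_p(y.sample(frac=1, random_state=k), cis, B=99, seed=k)[0]
              for k in range(10)]
        assert np.mean(ps) > 0.1

    def test_b_one_identical_permutation(self):
        gen = np.random.default_rng(13)
        n = 20
        y = pd.Series(np.ones(n) * 0 + gen.normal(size=n), index=[f"s{i}" for i in range(n)])
        cis = pd.DataFrame([gen.binomial(2, 0.3, n).astype(float)], columns=y.index)
        # a permutation can only tie or beat; with B=1 p is 1/2 or 1
        p, _ = eqtl.empirical_p(y, cis, B=1, seed=0)
        assert p in (0.5, 1.0)

    def test_no_cis_snps_rejected(self):
        y = pd.Series([1.0, 2.0])
        with pytest.raises(ValueError):
            eqtl.empirical_p(y, pd.DataFrame(columns=y.index))


class TestModuleQtl:
    def test_driving_snp_is_top_hit(self):
        hits = 0
        n_seeds = 15
        for seed in range(n_seeds):
            gen = np.random.default_rng(200 + seed)
            n = 150
            samples = [f"s{i}" for i in range(n)]
            g = gen.binomial(2, 0.3, n).astype(float)
            gsd = (g - g.mean()) / g.std()
            eig = pd.Series(0.5 * gsd + np.sqrt(1 - 0.25) * gen.normal(size=n), index=samples)
            geno = pd.DataFrame(
                [g] + [gen.binomial(2, 0.3, n).astype(float) for _ in range(99)],
                index=[f"rs{i}" for i in range(100)], columns=samples,
            )
            res = eqtl.module_qtl(eig, geno)
            hits += res.loc[res["p"].idxmin(), "snp_id"] == "rs0"
        assert hits >= 0.9 * n_seeds

    def test_eigengene_equals_dosage(self):
        gen = np.random.default_rng(14)
        n = 100
        g = gen.binomial(2, 0.4, n).astype(float)
        eig = pd.Series((g - g.mean()) / g.std(), index=[f"s{i}" for i in range(n)])
        geno = pd.DataFrame([g], index=["rs0"], columns=eig.index)
        res = eqtl.module_qtl(eig, geno)
        assert res["p"].iloc[0] < 1e-30

    def test_null_genome_few_discoveries(self):
        gen = np.random.default_rng(15)
        n = 100
        eig = pd.Series(gen.normal(size=n), index=[f"s{i}" for i in range(n)])
        geno = pd.DataFrame(
            gen.binomial(2, 0.3, size=(2000, n)).astype(float),
            index=[f"rs{i}" for i in range(2000)], columns=eig.index,
        )
        res = eqtl.module_qtl(eig, geno)
        assert res["significant"].sum() <= 1
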