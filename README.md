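# adiponet

Integrated multi-tissue expression analysis: weighted gene coexpression
networks, consensus modules and eigengene-network preservation across two
tissues, twin-design variance decomposition (familiality/heritability), and
cis-eQTL mapping with inverse-variance fixed-effects meta-analysis. A
synthetic-data module generates expression, trait, twin, and genotype data
with the statistical structure the analysis assumes, so the whole pipeline is
testable without any external download.

## Layout

| module                  | contents |
|-------------------------|----------|
| `adiponet.synthetic`    | two-tissue factor-model expression, logistic/linear traits, twin cohorts with six variance components, HWE genotypes with planted cis effects |
| `adiponet.preprocess`   | replicate averaging, expression filter, single-gene DE (OLS), between-depot DE (mixed model), Benjamini–Hochberg FDR, overlap summaries |
| `adiponet.network`      | Pearson correlation, soft-power adjacency, scale-free fit index, topological overlap, module detection, eigengenes, module membership, connectivities |
| `adiponet.consensus`    | consensus dissimilarity/modules, eigengene networks, preservation density D |
| `adiponet.association`  | eigengene–trait association, Fisher gene-set enrichment, eSNP prioritization, exact binomial/Bonferroni arithmetic |
| `adiponet.twin`         | six-component twin ML variance decomposition, familiality F, heritability h², Wilcoxon group comparisons |
| `adiponet.eqtl`         | genotype QC (MAF/call-rate/HWE exact test), cis-pair definition, per-study eQTL (OLS and twin mixed model), meta-analysis with Cochran's Q, permutation empirical p, module QTL |
| `adiponet.pipeline`     | YAML configuration, end-to-end orchestration, input validation, run manifest |
| `adiponet.io`           | TSV/VCF/GMT/JSON readers and writers |

## CLI

```sh
adiponet simulate --out-dir bundle --n-samples 100 --n-genes 1000 --seed 1
adiponet de --expr bundle/expression_tissue1.tsv \
            --annot bundle/sample_annotation.tsv \
            --response case_status --covariates gender,plate --out de.tsv
adiponet network --expr bundle/expression_tissue1.tsv \
                 --min-module-size 30 --target-r2 0.8 --out-dir net/
adiponet run --out-dir full_run --seed 1     # full synthetic pipeline
adiponet validate --expr ... --annot ...     # input cross-checks
```

Other subcommands: `assoc`, `enrich`, `varcomp`, `eqtl`. Exit codes:
0 ok, 1 input error, 2 stage failure.

## Notes on conventions

- Networks are unsigned: adjacency is `|cor|^beta`; the soft power is the
  smallest integer whose signed scale-free fit index reaches the target
  (default 0.8).
- Module detection is a fixed-height cut of the average-linkage dendrogram of
  `1 - TOM`, with the height expressed as a quantile of merge heights
  (default 0.7) and a minimum module size (default 30); clusters are labelled
  from a fixed color palette by decreasing size, `grey` = unassigned.
- The twin model is plain ML over nonnegatively-bounded variances; the
  likelihood factorizes over twin pairs. Familiality
  `F = (s2_pair + s2_zyg)/total`, heritability `h2 = 2*s2_zyg/total`.
- Benjamini–Hochberg, the HWE exact test, and the exact binomial tail are
  implemented directly (not delegated) and verified against enumeration
  oracles in the tests.
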