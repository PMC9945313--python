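# volemicrobiome

Statistical pipeline for paired pre/post probiotic-treatment microbiome
cohorts: median-of-ratios normalization, alpha/beta diversity with PERMANOVA
and dispersion testing, a per-animal ("vole-by-vole") paired
differential-representation procedure, ΔΔCt qPCR quantification, rank tests
with |Z|/√N effect sizes, and community-gated Spearman taxon–phenotype
correlations. A seeded synthetic-cohort generator with planted effects and
associations makes every stage testable without external data.

## Test

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the calibration and property criteria
(printed effect-size reproduction, exact Wilcoxon p, selection-rule
brute-force equivalence, UniFrac oracle equivalence, PERMANOVA type-I
calibration, planted-effect recovery, closed-form spot checks).

## CLI

```bash
# synthetic cohort with one planted effect
volemicrobiome simulate --seed 7 --outdir demo \
    --effect taxon003:F:live:2.0:0.2:1.0

# individual stages
volemicrobiome normalize --counts demo/counts.tsv --out demo/norm.tsv
volemicrobiome alpha --counts demo/counts.tsv --out demo/alpha.tsv
volemicrobiome beta --counts demo/counts.tsv --metric bray_curtis --out demo/bc.tsv
volemicrobiome permanova --distances demo/bc.tsv --metadata demo/metadata.tsv \
    --variable treatment --seed 1 --out demo/perm.tsv
volemicrobiome diff-vbv --counts demo/counts.tsv --metadata demo/metadata.tsv \
    --sex F --treatment live --out demo/vbv.tsv
volemicrobiome qpcr --qpcr demo/qpcr.tsv --assay L_reuteri --out demo/ddct.tsv
volemicrobiome correlate --counts demo/counts.tsv --metadata demo/metadata.tsv \
    --phenotypes demo/phenotypes.tsv --out demo/corr.tsv

# end-to-end from a YAML config (all thresholds default to the published rule)
volemicrobiome run-all --config config.yaml --set seed=1
```

Exit codes: 0 success, 2 validation failure, 3 stage failure.

### Minimal `config.yaml`

```yaml
counts: demo/counts.tsv
metadata: demo/metadata.tsv
tree: demo/tree.nwk
phenotypes: demo/phenotypes.tsv
qpcr: demo/qpcr.tsv
outdir: demo/out
seed: 1
```

## Selection rule

A taxon is reported by the paired per-animal procedure in a sex × treatment
group when both hold in the same direction:

- at least 5 of 8 animals (scaled proportionally for other group sizes) each
  change by |log2 fold change| ≥ 0.693 on size-factor-normalized counts, and
- the group mean over all animals is ≥ |1.25| (|1.8| for family-level
  display output).

Whole-group testing uses a simplified negative-binomial Wald statistic with
moment-based, trend-shrunken dispersions and BH-FDR at padj < 0.1 — an
approximation validated by null-calibration simulation, not a replica of any
specific tool.
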