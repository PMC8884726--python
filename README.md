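# asemap

**Allele-specific expression confounds in mutant RNA-seq.**

When mutant and sibling embryos from an incross are compared by RNA-seq,
genes near the causal mutation are dragged to homozygosity by linkage.  If
the two parental strains express a linked gene at different levels
(allele-specific expression, ASE), that gene shows up as "differentially
expressed" even though it has nothing to do with the mutation.  In outbred
model organisms such as zebrafish — where laboratory strains are highly
polymorphic — this produces clusters of spurious DE genes on the mutant
chromosome and can distort downstream interpretation (GO enrichments,
candidate pathways).

`asemap` implements the full computational toolkit for detecting,
quantifying and dissecting this confound:

| stage | what it does |
| --- | --- |
| `asemap.sim` | ground-truthed incross simulator: Haldane meiosis, recessive causal locus (~25% mutants), per-gene cis effects with E\|log2FC\| = 0.5, trans response genes, NB counts, pooled and per-embryo read sampling |
| `asemap.ldmap` | pooled LD mapping: per-SNP allele balance, LOESS smoothing, \|mutant − sibling\| difference curve, genome-wide peak, interpolation at gene starts |
| `asemap.de` | two-group negative-binomial DE (median-of-ratios size factors, trend-shrunk dispersions, Wald test, BH) |
| `asemap.linkage` | logistic regression P(DE) = logistic(α + β·LD), Wald test, odds ratio at max-vs-median LD, across-line BH adjustment |
| `asemap.enrichment` | per-chromosome binomial enrichment of DE genes (Bonferroni) and 20-Mbp mapping-window statistics |
| `asemap.haplotypes` | per-embryo strain haplotype calls in 1-Mbp windows, informative regions, recombinant-aware embryo grouping, region-wise ASE scan |
| `asemap.go` | GO over-representation with/without mutation-linked genes, Jaccard comparison, Cohen's-kappa term network |
| `asemap.classify` | four-genotype (compound-heterozygote) classifier: ASE-linked vs mutation-response DE genes |

## The statistics at the core

At each SNP retained after filtering (quality ≥ 100, covered in both
pools), the *allele balance* is `alt / (ref + alt)` per pool.  Both pool
curves are LOESS-smoothed along each chromosome and the LD statistic is
their absolute difference; its genome-wide maximum estimates the mutation
locus.  The effect of linkage on expression calls is tested with

    P(gene is DE) = logistic(α + β · LD(gene start)),

fitted by maximum likelihood (IRLS) with a Wald test on β, and summarised
as the odds ratio `exp(β · (LD_max − LD_median))`.  In a haplotype-resolved
wild-type cross, embryos are genotyped at strain-informative SNPs, windows
are called by majority vote (states A/A, A/B, B/B, NC, NA), embryos are
grouped by regional genotype, and DE between groups within *informative
regions* reveals cis-driven expression differences directly.

## Worked example

Simulate a pooled mapping cross (200 embryos, five 25-Mbp chromosomes,
recessive locus on chromosome 2 at 12.5 Mbp, 25% of genes with cis
effects), map the locus, call DE and test for linkage:

```python
import numpy as np, pandas as pd
from asemap import CrossConfig, simulate_incross, ldmap
from asemap.de import nb_test
from asemap.linkage import LinkageLogit, gene_ld_table
from asemap.enrichment import binomial_enrichment, nearby_de_genes

exp = simulate_incross(CrossConfig(seed=1))
profiles = ldmap.ld_profiles(exp.pool_sites, span=0.3, min_quality=100)
peak = ldmap.find_peak(profiles)

groups = pd.Series(np.where(exp.mutant, "mut", "sib"), index=exp.counts.columns)
de_res = nb_test(exp.counts, groups, reference="sib")

table = gene_ld_table(de_res, profiles, exp.gene_table[["chrom", "start"]])
fit = LinkageLogit.from_table(table).fit()
print(fit.summary())
```

Output:

```
peak 2:12329264 |mut-sib| = 0.576
50 DE genes of 2000 tested
Linkage logistic regression (DE ~ LD)
  n genes            2000
  n DE                 50
  alpha           -6.2698 (SE 0.4196)
  beta             9.6192 (SE 0.9206)
  Wald p(beta)   1.49e-25
  converged          True
odds ratio (max vs median LD): 114.5
```

The mapping peak lands ~170 kb from the simulated mutation.  The strongly
positive β says a gene's odds of being DE rise steeply with LD: a gene at
the peak is ~115× more likely to be DE than one at median LD — even though
every one of those DE calls is driven by cis polymorphism, not by the
mutation.  Chromosome-level enrichment and window statistics quantify the
same signal:

```
chrom  de_on_chrom  total_de         padj
    2           50        50 5.63e-35
44 of 50 DE genes within 20 Mbp of the peak (88%)
```

## Command line

Every stage is exposed as a subcommand of the `asemap` console script:

```bash
asemap simulate --config cross.yaml --seed 1 --out inputs/
asemap ldmap --vcf inputs/pools.vcf --span 0.3 --min-qual 100 --out ld/
asemap detest --counts inputs/counts.tsv --design inputs/design.tsv \
              --genes inputs/genes.bed --reference sib --out de.tsv
asemap linkage --de de.tsv --ld ld/ --genes inputs/genes.bed --out linkage.json
asemap enrich --de de.tsv --genes inputs/genes.bed --out enrichment.tsv
asemap run-all --out run/ --seed 1      # the whole chain plus report.json
```

`asemap run-all` also runs the haplotype/ASE scan, the GO comparison and
the four-genotype classifier on companion simulations and writes a
`report.json` summarising every stage.

## Layout

```
src/asemap/      library (sim, ldmap, de, linkage, enrichment,
                 haplotypes, go, classify, io, pipeline, cli)
tests/           pytest suite (unit, property and end-to-end tests)
scripts/         acceptance.py
docs/methods.md  models, assumptions, parameter choices, limitations
```
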