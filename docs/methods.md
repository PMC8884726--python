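# Methods

This note records the models behind each `asemap` component, the defaults
and why they were chosen, the numerical decisions, and what the bundled
simulator does and does not emulate.

## 1. The simulated cross (`asemap.sim`)

**Genomes.** Two parental strains, A and B (think AB and Tübingen).  Each
chromosome copy is a list of contiguous strain segments.  Meiosis follows
Haldane's model: crossover count per chromosome ~ Poisson(map length in
Morgans), breakpoints uniform, no interference.  Interference would change
the spacing of double crossovers but none of the statistics tested here
depend on it.  Two parent styles are provided:

* `mapping` — both parents heterozygous A/B along every chromosome, the
  idealised F2 situation of a mapping cross; the causal allele rides
  strain B.
* `mosaic` — each parental copy is an A/B mosaic (Poisson-placed switches,
  default 2 per copy per chromosome), emulating a line founded from two
  haplotypes and maintained by incrossing: parents are homozygous in some
  regions and heterozygous in others, which is what creates *informative
  regions* of every genotype combination.

**Expression.** Gene g with cis effect `c_g`: a strain-A copy contributes
`baseline/2`, a strain-B copy `(baseline/2)·2^c_g`, so the hom-B vs hom-A
expected log2 ratio is exactly `c_g` and a heterozygote expects
`baseline·(1 + 2^c)/2`.  Response genes are multiplied by `2^(t·dose)`
with dose 1 in causal homozygotes and 0.5 in carriers by default
(configurable to 0 for strictly recessive trans effects; intermediate
heterozygote levels are the observed norm in compound-het crosses).
Counts are negative binomial via gamma-Poisson mixing:
Var = μ + φμ².

**Reads.** Pooled SNP depths are Poisson(mean depth) per pool with alt
counts Binomial(depth, pool alt frequency computed exactly from pool
members' genomes).  Site qualities come from a two-component mixture
(90% Uniform(100, 999), 10% Uniform(0, 99)) purely so the quality filter
has something to do.  Per-embryo depths at informative SNPs are
Poisson(12) with binomial allele sampling; no sequencing error, indels or
multi-allelic sites are modelled (deliberate non-goals).

**Default conditions.** These are fixed once and shared by the tests and
the acceptance script:

| parameter | default | rationale |
| --- | --- | --- |
| chromosomes | 5 × 25 Mbp (mapping), 25 × 25 Mbp (SAT-style) | desk-scale genome; 25 chromosomes mirror the zebrafish karyotype |
| map length | 1 Morgan/chromosome | typical chromosome-scale genetic length |
| embryos | 200 (mapping: pools of ~50 mutants / ~150 siblings), 96 (SAT-style) | screen-sized clutch; 96 embryos is the plate-format cross the haplotype analysis targets |
| baseline mean | 500 counts | a well-quantified gene at ~20M reads/embryo; ASE measurement is only meaningful where counting noise is secondary |
| dispersion φ | 0.01 | same-clutch whole embryos at a fixed stage: biological CV ≈ 10% for well-expressed genes |
| fraction of ASE genes | 0.25 | ASE is widespread: a quarter of genes carry a nonzero cis effect |
| cis effect scale | c ~ N(0, 0.5·√(π/2)) so E\|c\| = 0.5 | calibrated to the mean absolute hom-vs-hom log2FC such crosses exhibit |
| pooled depth | 60× per pool per SNP | pooled RNA-seq of ~45+ individuals |
| embryo SNP depth | 12× | RNA-seq genotyping depth at expressed SNPs |
| SNP polarity | alt allele on strain B (mapping) / random (SAT) | a reference genome derived from one strain puts most alternate alleles on the other strain, which is what makes pooled allele-balance curves smooth; strain-of-origin conversion makes polarity irrelevant in the SAT analysis |

Identical configs (including seed) give bit-identical experiments; all
sampling flows through one `numpy` generator seeded from the config.

## 2. LD mapping (`asemap.ldmap`)

Sites are filtered (quality ≥ 100, nonzero depth in both pools), the
allele balance `alt/(ref+alt)` is computed per pool, and each pool's
balances are smoothed by LOESS — local linear regression with tricube
weights over the span-nearest neighbours (span = fraction of SNPs,
default 0.3, exposed as `--span`).  The smoother is
`statsmodels.lowess` with zero robustness iterations; a test verifies it
against a direct weighted-least-squares evaluation.  The optional
`delta_frac` argument enables the standard LOESS anchor-point speed-up
(exact fits at points at least `delta_frac·range` apart, linear
interpolation between); the default is 0 (exact everywhere).

Curves are evaluated at the retained SNP positions — no artificial grid —
and clamped to [0, 1].  The LD statistic is the pointwise
|mutant − sibling| difference; the peak is the genome-wide argmax over SNP
positions with ties broken toward the smallest (chromosome, position).
LD at an arbitrary position (a gene start) is linear interpolation,
clamped at chromosome ends.  The peak is a point estimate; no confidence
interval is attempted.

Under the simulated mapping cross the mutant pool approaches allele
balance 1 at the causal locus while siblings sit at 1/3 (the 2:1
het:hom-wt mix), giving an asymptotic difference of 2/3.

## 3. Differential expression (`asemap.de`)

A transparent two-group NB caller, *not* a DESeq2 re-implementation
(externally computed results import via `asemap.io.read_de_results`):

1. size factors by median-of-ratios over genes nonzero in all samples,
   rescaled to geometric mean 1;
2. genes with fewer than 5 total raw counts are excluded from testing
   (stabilises dispersion estimation at small n);
3. per-gene dispersion by pooled within-group method of moments
   (floor 1e-8), shrunk with weight w = 0.5 toward a parametric trend
   `φ(μ) = a + b/μ` fitted across genes;
4. Wald statistic on log2FC with
   SE² = ((1/m_A + φ)/n_A + (1/m_B + φ)/n_B)/ln²2; a group mean of zero is
   replaced by the continuity value 0.5/n;
5. the statistic is referred to Student-t with
   df = residual df/(1 − w)² (= 4× residual df at the default w): the
   cross-gene trend contributes information to each per-gene dispersion,
   and this reference keeps small-sample type-I error near nominal while
   tending to the usual normal approximation as n grows;
6. BH adjustment over tested genes; DE ⇔ adjusted p < 0.05.

Measured behaviour (tests): null fraction p<0.05 ≈ 0.049 at 6v6; pure-null
BH discoveries essentially absent; a 4-fold spike at mean 500, φ = 0.05,
3v3 detected in ≥95% of replicates.

## 4. Linkage logit (`asemap.linkage`)

`P(DE) = logistic(α + β·LD)` fitted by IRLS (Newton steps on the observed
information), convergence at max parameter change < 1e-8 or 100
iterations; SEs from the inverse observed information; two-sided Wald p
for β.  Perfect separation is detected (saturating linear predictors /
singular information) and flagged as non-converged rather than reported
with meaningless SEs.  The odds-ratio summary `exp(β·(LD_max − LD_median))`
uses the maximum and median of the *gene-level* interpolated LD values —
the quantity actually entering the regression — a deliberate reading,
since max/median over raw SNP values would mix scales.  P-values from
several lines are BH-adjusted with the star convention *** < 0.001,
** < 0.01, * < 0.05.

## 5. Chromosome enrichment (`asemap.enrichment`)

One-sided exact binomial tail P(X ≥ k) with n = total DE genes and
p0 = chromosome's share of annotated genes; Bonferroni factor = number of
chromosomes tested within the experiment (enrichment, not depletion, is
the hypothesis; p0 is gene-count based, matching a "uniform over genes"
null).  Genes without a chromosome assignment are pooled into an
"unplaced" stratum, counted in totals but not tested.  The window report
counts DE genes in a closed window centred on the mapping peak (truncated
at chromosome bounds) and reports exact and integer-rounded percentages;
the random-window calibration samples windows uniformly over valid starts
genome-wide (chromosome chosen proportional to its valid-start count).
For uniform genes the expected captured fraction is exactly
window/length per chromosome — the basis of the analytic check in the
tests.

## 6. Haplotype calling and the ASE scan (`asemap.haplotypes`)

Informative SNPs are sites homozygous-reference in one founder and
homozygous-alternate in the other (with genotype-quality ≥ 100 and mean
depth ≥ 10 filters when those fields are present).  Embryo sites are
genotyped by allele fraction: no-call under 5 reads, hom-ref ≤ 0.1,
het in [0.3, 0.7], hom-alt ≥ 0.9, otherwise no-call.  These thresholds
are this package's caller — validated against simulation truth, with no
equivalence claimed to any external caller.  Calls are converted to
strain space and windows called by majority vote in fixed 1-Mbp bins
anchored at coordinate 1; a window is NA below 5 informative calls or on
a tied vote, and NC when the winning genotype is impossible given the
parents' window genotypes.  Majority vote (not an HMM) is the method:
no smoothing across windows is applied.

Informative regions are maximal runs of adjacent windows where the
parental combination permits ≥ 2 offspring genotypes, the possible-set is
constant (a different set means a different grouping), and ≥ 80% of
embryos have a non-NA call (`min_callable_fraction`, this package's
quantification of "sufficient depth").  Within a region each embryo gets
its single regional genotype, or — for recombinants — the genotype of its
longest contiguous window run; ties are left unassigned, and NC/NA
windows break contiguity without forming groups.

The ASE scan runs the NB test per region for each available contrast
(hom-B vs hom-A, het vs either hom) with ≥ 2 embryos per side, annotating
every DE gene with whether it lies inside the defining region.  On
simulated crosses, callable-window accuracy exceeds 99% (truth defined as
the modal true genotype over the window's SNP positions — a window
containing a breakpoint has no single genotype) and isolated breakpoints
are localised within ±1 window; breakpoints inside the first or last
window of a chromosome are below window resolution by construction.

## 7. GO comparison (`asemap.go`)

Classic one-sided hypergeometric over-representation with BH adjustment
(threshold on *adjusted* p < 0.05; the choice is configurable), universe
defaulting to the genes tested for DE, terms under 5 annotated universe
genes skipped.  GO ancestry propagation is not applied — supply a
pre-propagated annotation if the true-path rule is wanted.  The
linked-gene filter removes DE genes on the mutant gene's chromosome but
keeps the mutant gene itself.  Set similarity is the Jaccard coefficient;
two empty sets are defined to agree (1.0, logged).  The term network
connects enriched terms whose membership vectors over the universe have
Cohen's kappa > 0.4.

## 8. Four-genotype classifier (`asemap.classify`)

The verbal patterns — "expression tracks one parental wild-type
chromosome" vs "expression tracks functional-allele dosage" — are
operationalised as linear models on log(normalised count + 1):

* ASE model: two means over a wild-type-chromosome partition
  ({+/+, m1/+} vs rest, or {+/+, +/m2} vs rest; best of the two);
* response model: mean linear in dosage (2, 1, 1, 0; per-allele severity
  weights configurable);
* null model: one mean.

A call requires the winning model to beat **both** the rival and the null
by ≥ 2 AIC units; otherwise the gene is AMBIGUOUS.  The null gate is this
package's addition to the two-model race: selecting the better of two ASE
partitions wins the AIC race on pure noise often enough that, without it,
noise genes would be called at well above the intended rate; requiring
the winner to also beat "no pattern at all" keeps pure-noise calls below
10% while leaving planted patterns (recovered at ≥ 80%) untouched.
Response calls additionally require the dosage ordering: compound-het
mean deviating from wild type with both heterozygote means inside the
wt–comphet span (tolerance 25% of the span).  Group means are exported so
the patterns can be inspected directly.  Counts are size-factor
normalised first, making calls invariant to global depth.  A Gaussian
log-scale model (not an NB GLM) is adequate at these group sizes and
keeps AIC comparisons transparent.

## 9. Problem sizes

The test suite and acceptance script use the simulator at the default
conditions above: full-size runs (96 embryos × 25 chromosomes for the
haplotype analysis, 200-embryo pools with 5,000 SNPs/chromosome × 20
replicates for peak recovery, 200 null replicates at n = 30,000 genes for
linkage calibration, 500 replicates for the Bonferroni FWER check).
These sizes were chosen to keep Monte-Carlo error well inside the
assertion bands.

## 10. What passing tests do and do not show

The simulator draws effects from symmetric, stationary distributions,
places genes and SNPs uniformly, and models no sequencing error, mapping
bias, batch effects, library composition bias or expression-dependent
pooling weight (pools weight embryos equally).  Consequently the tests
demonstrate the *statistical machinery* — filters, smoothing, calibration,
grouping, classification — under a faithful genetic model, not robustness
to the technical artefacts of real libraries.  Reference-mapping bias in
particular (alt reads mapping less efficiently) would shift real allele
balances away from 0.5 in a way the simulator deliberately omits.  The
known-limitations list also includes: two-pool designs only, two parental
haplotypes only (no outgroup alleles), gene-level features throughout,
and no confidence interval on the mapping peak.
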