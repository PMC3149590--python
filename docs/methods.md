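# Methods

`taintscan` maps quantitative trait loci (QTL) for boar-taint compounds
(androstenone, skatole, indole and related sex steroids, measured in ppm)
in paternal half-sib pig designs. It implements two genome scans on the
same mixed model — a per-SNP association scan (GWAS) and a combined
linkage-disequilibrium/linkage scan (LDLA) over haplotype clusters — with
chromosome-wise and genome-wide significance, QTL region calling and
cross-breed confirmation, plus a synthetic-data generator that emulates
the test-station study design with known ground truth.

## Phenotype transform

Taint compounds have skewed distributions and assay detection limits;
values below the limit are recorded as 0. Every measurement is
transformed as `ln(ppm + limit)` before model fitting, with per-trait
limits of 0.05 ppm (androstenone), 0.01 ppm (skatole, indole), 0.5 ppm
(testosterone, estrone sulphate) and 0.04 ppm (17β-estradiol). Adding
the limit keeps censored records in the analysis at the transform's
floor rather than discarding them.

## Mixed model and scan statistic

For a phenotyped sample of n boars,

    y = X b + u + m + e
    u ~ N(0, A σ²_poly),  m ~ N(0, Z Z' σ²_term),  e ~ N(0, I σ²_e)

* `X`: intercept, test-station, age at entering the test (days), days in
  test, litter mates born alive. Aliased columns are dropped greedily,
  first-come kept, so reparameterisations do not change the fit.
* `A`: pedigree additive (numerator) relationship matrix from the
  tabular recursion; unknown parents are unique unrelated founders. It
  accounts for the strong half-sib family structure.
* `Z`: the marker term. GWAS: the 0/1/2 dosage of the (arbitrarily
  oriented) '1' allele, a single column; missing dosages imputed to the
  SNP mean. LDLA: the haplotype-cluster incidence per individual (rows
  sum to 2). In both cases the marker effect is a *random* effect with a
  single variance.

Variance components are estimated by REML; the scan statistic at a
position is `LnLikratio = lnL(full) − lnL(null)` where the null (no
marker term) is fitted once per trait and reused along the genome.
`2·LnLikratio` is referred to χ²(1) for the pointwise p-value. Because
the marker variance is tested on the boundary of its parameter space the
χ²(1) reference is conservative (the true null is ≈ a 50:50 mixture of
χ²(0) and χ²(1)); this convention is kept deliberately and its
conservatism is verified by the null-calibration test rather than
corrected with a mixture.

### REML numerics

The criterion is −½[log|V| + log|X′V⁻¹X| + y′Py] with constants dropped
consistently so they cancel in ratios. `A` is eigendecomposed once per
dataset; rotating the model by its eigenvectors makes V diagonal plus a
low-rank marker term, so each likelihood evaluation costs O(n(p+k)²)
via the Woodbury identity (scalar Sherman–Morrison for the GWAS rank-1
case). σ²_e is profiled out analytically; the remaining log variance
ratios are maximised by bounded L-BFGS-B (ratio bounds 1e-8…1e8,
criterion tolerance 1e-9, fixed start, no random restarts — fits are
deterministic). If the quasi-Newton line search stalls on
finite-difference noise a Nelder–Mead polish finishes the fit. Ratios
below 1e-7 are reported as a zero variance. A constant response, or
n ≤ rank(X)+1, is rejected. LnLikratio is clamped at 0 against
numerical undershoot of the nested null. Genome scans warm-start each
fit from the previous marker's optimum (the optimum is independent of
the start; this only saves iterations).

## Haplotype clustering (LDLA)

At each tested position (every marker by default) phased haplotypes are
grouped by a binary identity rule: two haplotypes are "completely
correlated" iff the number of consecutive agreeing alleles scanning left
from the focal marker (inclusive) plus scanning right from the next
marker, each run stopped at the first mismatch or chromosome end, totals
≥ 10. Otherwise they are uncorrelated. Equivalently, a pair is identical
iff it agrees on some window of 10 consecutive markers starting within
[focal−9, focal+1]; hashing rows per window evaluates the relation in
O(10·n) instead of all-pairs scanning (the equivalence is exercised
against a direct all-pairs oracle in the tests).

The pairwise relation is not transitive, so a closure turns it into a
partition. The default is **greedy reference assignment**: the first
unassigned haplotype founds a cluster and collects every haplotype
identical to it. Every member is then identical to its reference, which
honours the completely-correlated-or-uncorrelated semantics. The
alternative single-linkage closure (connected components) is available
(`closure="single"`) but collapses at realistic haplotype counts: a
chance ≥10-marker agreement between unrelated haplotypes occurs at
~10⁻³ per pair, and with ~10³ haplotypes (≈5·10⁵ pairs) those stray
edges chain essentially all clusters together, flattening the LDLA
profile. This failure mode reproduces readily on simulated data and
motivated the default.

A position where all haplotypes fall into one cluster has no contrast;
its LnLikratio is fixed at 0 and the position is flagged uninformative.

## Significance

* **Chromosome-wise (CWS)**: the upper bound for the tail of the
  supremum of a 1-df χ² scan process,
  `cws_p = Pr(χ²₁ > c) + V·e^{−c/2}/√(2π)`, where `c = 2·LnLikratio`
  and `V = Σ|√(2LR_i) − √(2LR_{i−1})|` is the total variation of the
  √statistic along the chromosome. The chromosome peak uses its own
  statistic; per-position CWS values share the chromosome's V, so the
  bound is monotone in the statistic and never below the pointwise p.
  Being a bound, it is conservative — verified by Monte-Carlo null
  calibration.
* **Genome-wide (GWS)**: `gws_p = min(1, 18 × cws_p)` — a Bonferroni
  step over the 18 porcine autosomes. Reports round p-values to 3
  decimals; machine-readable output keeps full precision.
* Positions/QTL with p < 0.05 are significant at the respective level.

## Region calling and cross-breed confirmation

A region is seeded at each local profile peak with cws_p < 0.05. Its
extent is the contiguous run of positions with LnLikratio ≥ peak − 1.92
(so 2·drop equals the χ²₁ 95% cutoff, a 1-LOD-like support interval);
regions on the same chromosome separated by < 1 Mb are merged. The
region class is GWS if the peak's gws_p < 0.05, else CWS. The
variance explained by a fitted position is reported as
`100·σ²_term/(σ²_term + σ²_poly)` — the marker share of the genetic
variance; at a selected peak it is upward-biased (winner's curse).
How the source analysis derived its reported Mb confidence intervals is
not documented; this drop/merge rule is this package's own construction,
isolated in one configurable function.

Two breeds' region lists are compared by bp overlap on the same
chromosome: an overlapping pair is **confirmed** iff one member is GWS
and the other at least CWS (p < 0.05); all other regions are
breed-specific.

## Synthetic data generator

The generator emulates a boar test-station design with one phenotyped
generation:

* **Pedigree**: `n_sires` unrelated sires (default 92, the Landrace
  arm's family count), each mated to distinct unrelated dams, one
  offspring per dam, family sizes uniform in [7, 24] — paternal
  half-sib families.
* **Founder haplotypes**: a pool of `founder_pool_size` (default 64)
  template haplotypes per chromosome, built as mosaics of ancestral
  block variants: blocks of `founder_block_cM` (default 5 cM) with
  `founder_block_variants` (default 4) variant sequences each, per-site
  allele frequencies uniform in [0.2, 0.8], monomorphic sites repaired.
  Founders copy whole templates with per-site mutation (default 0.02).
  This yields linkage disequilibrium that is strong locally and decays
  with map distance — the feature the identity-rule clustering needs —
  without a coalescent simulation. The pool size controls long-range
  (template-frequency) LD and was chosen to make the scans' localization
  behaviour realistic; it does not model any specific breed's LD decay.
* **Gene drop**: each non-founder inherits one recombinant gamete per
  parent; crossovers are a no-interference Poisson process on the cM
  scale (count ~ Poisson(length/100), positions uniform) — the Haldane
  model, consistent with the map-function conversions. Phase is
  recorded, so truth-phased haplotypes are available downstream.
* **Phenotype**: log-scale value = μ + station + β·(age, days, litter)
  + Σ QTL effects + u + e, exponentiated to ppm and censored at the
  detection limit (recorded 0 below it). Founder breeding values
  u ~ N(0, σ²_poly); offspring u = ½(u_sire+u_dam) + N(0, ½σ²_poly)
  (non-inbred Mendelian sampling; inbreeding is ignored, adequate for a
  single non-inbred generation). Each QTL sits at the marker nearest its
  configured cM position and its allele-substitution effect is
  back-solved so it explains the configured fraction of the genetic
  (QTL + polygenic) variance given the realized dosage variance; a
  monomorphic realization is an error naming the locus.
* **Degradation**: the unphased 0/1/2 matrix gets missing entries
  (default 0.5%) and random genotype errors (default 0.05%), giving the
  QC filters something to catch; truth phase is kept separately.

Default variances σ²_poly = σ²_e = 0.5 log-ppm² give heritability 0.5,
inside the reported 0.25–0.88 range for androstenone; the default single
QTL explains 6% of genetic variance, the top of the 1–6% range the
full-scale study attributes to individual significant regions. Station
effects (3 stations, ±0.1), covariate coefficients (0.01/day age,
0.005/day on test, −0.02/litter mate) and covariate distributions are
plausible magnitudes for log-scale taint data; they exist to exercise
the fixed-effect machinery, not to match any published estimate. One
trait is simulated per run.

### What the generator does not emulate

Breed-specific LD decay, multi-generation selection, genotyping-batch
artefacts, sex chromosomes, multi-trait correlations between compounds,
and assay measurement error beyond the detection-limit censoring.
Passing tests therefore demonstrate correctness of the machinery and
calibration under this idealised design, not performance on any real
pig population.

## Problem sizes in tests and the acceptance script

Simulation-backed checks use scaled designs chosen to keep the suite
practical while preserving the study's structure: null calibration uses
500 scans of a 40-family, 100-marker chromosome; power/recovery uses
100 replicates of the full 92-family design on a 50 cM, 100-marker
chromosome (marker spacing 0.5 cM, so the 10-marker identity window
spans one LD block); the two-breed comparison uses 40 families per
breed, 3 chromosomes × 120 markers. At that reduced two-breed sample
size a 6%-of-genetic-variance QTL almost never reaches genome-wide
significance, so the confirmation-logic replicates simulate their QTL
at 20% of the genetic variance — the fraction that reproduces, at
n = 400, the detection noncentrality a 6% QTL has at the full ~1400-boar
scale — since that test checks the classification rule, not power at
full scale. `scripts/acceptance.py` repeats these analyses at
somewhat smaller replicate counts and reports the measured rates.

## Known limitations

* LDLA requires phased haplotypes (the generator's truth phase or an
  external phaser); no phasing of real unphased genotypes is included.
* The χ²(1) reference and the scan bound are both conservative;
  reported p-values are upper bounds, and power comparisons against
  methods with exact references would be pessimistic.
* Variance explained at a selected peak is upward-biased.
* The Mendelian-error filter only detects opposite-homozygote
  parent-child conflicts, as in the source protocol; 'non-informative'
  SNP removal is implemented as monomorphic-within-cohort, one of
  several defensible readings.
* `call frequency > 0.10` is reproduced as printed even though 0.90
  would be conventional; both it and all other thresholds are strict
  inequalities as printed.
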