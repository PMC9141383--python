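# Methods

## Data model and panel

The unit of analysis is an individual's unordered genotype calls across a
fixed panel of bi-allelic SNPs plus a group label. Genotypes are
canonicalised to a fixed allele order ("GA" and "AG" are the same call);
missing calls are explicit (`NA` in the TSV dialect). The default panel is
the eight-polymorphism concussion-candidate set (ANKK1 rs1800497, APOE
rs429358/rs7412/rs405509, BDNF-AS rs6265, COMT rs4680, MAPT rs10445337,
NOS3 rs2070744). The panel loci lie on six different chromosomes, which is
why the simulator and the expected-score enumeration treat loci as
statistically independent (linkage equilibrium).

### APOE ε derivation

rs429358 and rs7412 jointly define the ε haplotypes over (rs429358, rs7412):
ε2 = (T,T), ε3 = (T,C), ε4 = (C,C); the rare fourth haplotype ε1 = (C,T) is
excluded by convention. Each SNP-genotype pair is resolved by enumerating
both phasings. The doubly heterozygous call (C/T at both SNPs) admits two
resolutions, ε2/ε4 and ε1/ε3; the default convention assigns ε2/ε4 (the
standard choice that avoids ε1), with an `ambiguous="exclude"` option that
treats the call as missing instead. Pairs resolvable only through ε1
(e.g. rs429358 C/C with rs7412 T/T) are flagged unresolvable and the
individual is treated as missing for all ε-based analyses; the same applies
when either SNP call is absent. Only ε4 carriage (ε4+/ε4−) feeds any
downstream statistic.

## Total genotype score

Seven additive components — six SNPs scored codominantly 2/1/0 and the ε
attribute scored 2 (ε4−) or 0 (ε4+), never 1 — are summed and rescaled by
100/14 to a 0–100 range, giving a 15-point grid. Scores are kept at full
precision; the conventional one-decimal display (92.9, 21.4) is applied
only at output. Three builtin schemes are provided:

* `literature` — each SNP's "preferable" homozygote per the prior
  concussion literature (ANKK1 GG, rs405509 GG, BDNF-AS CC, COMT AA,
  MAPT CC, NOS3 TT = 2);
* `data_led` — rs405509 (TT = 2) and COMT (GG = 2) reversed to follow
  genotype frequencies observed in elite athletes;
* `literature_nos3_flipped` — the literature scheme with NOS3 reversed
  (CC = 2). Published accounts of which NOS3 homozygote the literature
  scoring preferred are internally inconsistent, so both orientations are
  packaged and none is asserted as canonical; analyses that need an
  unambiguous scheme (including the acceptance script) use `data_led`.

**Missing components.** The default policy is complete-case: an individual
with any unscorable component has no TGS and is excluded from TGS analyses.
An optional policy imputes a missing component by its expected score under
the individual's group frequencies, still flagged incomplete.

**Summaries.** SD uses the n−1 denominator. Kurtosis is excess kurtosis
with the standard small-sample bias correction
G2 = ((n+1)·g2 + 6)(n−1)/((n−2)(n−3)), and its standard error is the
closed form SE(kurt) = 2·SE(skew)·√((n²−1)/((n−3)(n+5))) with
SE(skew) = √(6n(n−1)/((n−2)(n+1)(n+3))) — the formulas used by the
mainstream commercial statistics packages this workflow historically ran
in. Degenerate (constant) samples report kurtosis as not applicable.
Quartile cut-points use linear-interpolation percentiles of the pooled
two-group distribution; the extreme-quartile comparison counts scores at or
beyond the pooled 25th/75th percentiles and excludes the middle half.

**Expected TGS.** Under locus independence the exact TGS distribution is
computed by enumerating the full component-score product space (≤ 3⁶×2 =
1458 cells) with cell probabilities from the frequency table; simulated
cohort means are validated against this enumeration.

## Association statistics

* **Chi-square**: Pearson test of independence without Yates continuity
  correction (the uncorrected statistic is what reconciles with the
  published odds ratios); Cohen's w = √(χ²/N) attached. Empty marginals are
  rejected with the offending row/column named.
* **Power**: the test statistic under the alternative is noncentral
  chi-square with noncentrality λ = N·w²; the solver finds N with
  P[χ²_nc(df, Nw²) > χ²_crit(α, df)] = power by Brent root-finding and
  reports both the real-valued solution and the smallest sufficient
  integer. df defaults to 1, which is the setting that reproduces the
  standard planning numbers for this design (785 at w = 0.1, 465 at
  w = 0.13, α = 0.05, power 0.8).
* **Odds ratios**: ad/bc with Woolf's log-method CI; the Haldane–Anscombe
  +0.5 correction is applied only when a cell is zero. A proportions form
  (p1/(1−p1))/(p2/(1−p2)) supports computing ORs directly from published
  percentages.
* **ROC/AUC**: the Mann–Whitney pair-counting statistic (ties ½),
  implemented via ranks; CI by Hanley–McNeil by default with DeLong's
  covariance-based variance behind a flag; the p-value against AUC = 0.5
  is a normal approximation using the same SE. The CI method choice
  matters little at these sample sizes and is not load-bearing anywhere.
* **t-test**: two-sided pooled-variance Student's by default (Welch by
  flag), matching the historical package-default convention.

## MDR

Attributes default to the seven score components (six three-level SNPs +
binary ε4 carriage); a mode with rs429358 and rs7412 as separate raw
three-level attributes is available. Complete-case filtering is applied
over the attribute set before the search. For each attribute combination,
training individuals are cross-tabulated into multilocus cells and a cell
is labelled **high-risk iff cases/controls ≥ T**, with T the training
split's overall case:control ratio, ties labelled high, and case-only cells
high. This rule provably maximises training balanced accuracy over all
2^cells labellings, which is what justifies ranking combinations by it.
Cells unseen in training predict low-risk at evaluation time (an `abstain`
policy that drops such individuals is available).

Cross-validation is stratified k-fold (default 10) with a seeded shuffle;
`folds=1` degenerates to whole-sample selection, which is checked against a
brute-force enumeration oracle in the tests. Per fold and combination size,
the combination with the highest training balanced accuracy wins (ties
broken lexicographically for determinism) and is evaluated on the held-out
fold. Per size, the modal winner's CVC is the number of folds that selected
it, and its mean training/testing balanced accuracies are computed by
evaluating it in every fold. The final model maximises CVC, ties broken by
mean testing balanced accuracy. Balanced accuracy (mean of sensitivity and
specificity) rather than raw accuracy is used throughout because the
default design is unbalanced (635 cases vs 722 controls).

**Carrier combinations.** An individual carries an allele combination iff
they carry ≥ 1 copy of the listed allele at every listed locus; proportions
are over individuals with complete calls at those loci. An allele-level
mode divides, per individual, the minimum per-locus dosage of the listed
alleles (the largest number of haplotypes that could carry the combination
under unknown phase) by 2N chromosomes; it exists for sensitivity analysis
and nothing in the default workflow depends on it.

## Synthetic cohorts

The generator draws each locus independently from per-group genotype
category probabilities (`genotype` mode, treating the packaged published
proportions as exact) or from Hardy–Weinberg proportions at the implied
allele frequency (`hwe` mode). The packaged table holds the published
athlete/non-athlete frequencies; positional subgroups (rugby union
forwards/backs, rugby league) are drawn from the pooled athlete
frequencies, since per-position tables were never published. APOE is drawn
as two ε haplotypes per individual with the ε4 haplotype frequency solved
from the target carrier rate (f4 = 1 − √(1 − P(ε4+))) and the remainder
split ε2:ε3 = 0.08:0.77 (a typical European ratio), then back-converted to
rs429358/rs7412 genotypes; only the ε4± rate affects any statistic in
scope. Missingness is applied per locus, completely at random.

Penetrance plants relabel individuals case/control from their joint
genotype at two target loci. The XOR plant (risk `high` iff exactly one
locus heterozygous) has exactly flat single-locus marginals when both loci
sit at allele frequency ½ — the `balanced_validation_table()` provides that
regime — making it the canonical positive control for the interaction
search.

**What the generator does not emulate:** linkage disequilibrium, population
stratification and relatedness, genotyping error and batch effects,
non-random missingness, and any true genotype–phenotype association beyond
the planted penetrance. Tests passing under the generator therefore
validate the statistical machinery under the study's stated assumptions,
not claims about real cohorts.

## Problem sizes and reproducibility

Every stochastic routine takes an explicit seed (`numpy.random.default_rng`)
and is bit-reproducible; the pipeline embeds its seed in every output and
reruns are byte-identical. The test suite and acceptance script use cohort
replicates at the study's group sizes (635/722, averaged over 20 seeds for
cohort-level quantities), 10⁵-individual draws for frequency-convergence
checks, 1000-replicate null simulations for type-I-error calibration, and
n = 800–1000 cohorts for the MDR validation scenarios — sizes chosen so
Monte-Carlo error is comfortably below the assertion tolerances.

## Known limitations

* The quartile comparison pools both groups for cut-points; per-group
  quartiles are a defensible alternative the package does not implement.
* The MDR permutation test used by some MDR software for p-values is out of
  scope; significance claims about combination frequencies come from the
  chi-square machinery instead.
* HWE testing covers bi-allelic SNPs only; the derived ε attribute is not a
  genotype and is never HWE-tested.
* The ε2:ε3 split in the simulator is a fixed constant, so ε-diplotype
  frequencies beyond ε4± should not be interpreted.
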