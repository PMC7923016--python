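# Methods

`breedauth` implements the computational chain by which a small-breed Herd
Book can (i) redefine its breed standard around two DNA markers — the
Extension locus (*MC1R*, alleles E+, ED1, ED2, EP, e) and the
vertebral-number gene *NR6A1* (alleles T/C) — and (ii) quantify how well
those markers authenticate "mono-breed" meat against other breeds and wild
boar. This note records the models, the numerical choices, and the design
decisions taken where more than one reasonable option existed.

## Allele calling from restriction patterns

The five *MC1R* alleles are resolved from three PCR-RFLP digestions plus a
2-bp indel sized on a capillary sequencer. The published enzyme behaviour is
a partial truth table: *Hha*I cuts every allele except `e`; *Bst*UI cuts
every allele except `e` and `ED1`; *Bsp*HI cuts `ED2` and `EP` but not `E+`;
the indel fragment is 168 bp for `ED2` and 170 bp for `EP`. The caller walks
that table in order (HhaI → BstUI → BspHI → indel), so cells the table does
not define (e.g. *Bsp*HI on `e`) are never consulted. A pattern whose known
fields contradict the published behaviour of the called allele raises an
inconsistency error, and a branch reached with an unknown required field
raises an ambiguity error naming the missing assay — the caller never
guesses outside the published table. Heterozygous animals produce
superimposed band patterns; the package deliberately takes already-scored
per-allele patterns as input and does not interpret mixed gel images.

The *NR6A1* call is a single *Msp*I digestion that cuts when the wild-type
(C) allele is present: cut → C, uncut → T.

## Herd-Book compliance

The shipped default standard admits *MC1R* genotypes `e/e`, `E+/e`, `E+/E+`
and *NR6A1* `T/T`, and constrains three adult morphological descriptors
(black-and-tan coat, ears bent forward and parallel to the muzzle, dorsal
bristle mane present). Young animals are exempt from the phenotype rules:
red coat, non-standard ears and an absent mane occur transiently in juveniles
and are recorded but never grounds for exclusion.

Exclusion reasons are evaluated in a fixed precedence — phenotype, then
MC1R, then NR6A1 — and an animal failing several rules records all of them
but is *counted* once, under the first. This single-primary-reason rule is
what allows a filtered sample to report "1 phenotype + 14 genotype"
exclusions without double-counting an animal that fails both stages. A
record missing a genotype at a standard locus is *indeterminate*, a third
status distinct from exclusion, and such animals are listed separately.
The filter is idempotent: re-filtering its retained set excludes nobody.

## Frequencies and Hardy–Weinberg testing

Frequencies derived from genotype counts are exact rationals
(`fractions.Fraction`), so per-locus frequencies always sum to one; only
externally read tables carry float rounding. Read frequency tables are
validated to sum to one within 0.015 per breed/locus — printed 3-decimal
panels legitimately drift by rounding (e.g. 0.192 + 0.809 = 1.001) —
while internally derived tables are exact by construction.

Two Hardy–Weinberg tests are provided, because the original software's
method is not recorded: a Pearson chi-square on observed vs expected
genotype counts (no continuity correction, no rare-genotype pooling; df =
k(k−1)/2 for k alleles) and, for two alleles, the conditional exact test
that enumerates all heterozygote counts compatible with the observed allele
counts and sums the probabilities of outcomes no more probable than the
observed one. The two are *not* interchangeable at moderate sample sizes:
on the retained-sample counts (222/109/11) the chi-square p is 0.590 and
the exact p is 0.727, a 0.14 gap driven by the 0.126 probability atom of
the observed table — both comfortably satisfy the reported bound p > 0.10.
Probability ties in the exact test (and in the differentiation test below)
are resolved with a 1e-12 tolerance on log-probabilities.

## Pairwise Fst (Weir–Cockerham)

Differentiation between two populations is the Weir & Cockerham (1984)
moment estimator: for each allele at each locus the among-population (a),
among-individual (b) and within-individual (c) variance components are
computed from sample sizes, allele frequencies and observed heterozygote
frequencies, and the multi-locus estimate is Σa / Σ(a+b+c) over all alleles
and loci. Components are returned for audit. A locus monomorphic in both
populations contributes (0,0,0); if no locus is informative the estimate is
undefined and an error is raised rather than returning 0. The estimator is
cross-validated in the test suite against an independently coded
nested-ANOVA formulation (mean squares → variance components) to 1e-10.

Note that theta for two identical samples is *not* exactly zero: with zero
among-population variance the a-component reduces to −(p̄q̄ − h̄/4)/(n̄−1)
per allele, giving small negative estimates (≈ −1.5e-3 for the retained
sample vs itself). This is the expected behaviour of the unbiased moment
estimator, and matches the small negative values reported for
undifferentiated population pairs; tests assert |theta| < 0.01 rather than
machine zero.

## Exact test of genic differentiation

The genic test conditions on the allele-count margins of the 2 × k
populations-by-alleles table. The p-value is the total conditional
probability of tables as or less probable than the observed one. Small
table spaces (up to 2·10⁵ tables; every 2 × 2 table in practice) are
enumerated exactly by depth-first search over the first row with
log-probabilities from `gammaln`. Larger spaces use a Metropolis Markov
chain over tables with fixed margins: each move shifts one allele between
two columns of the 2 × 2 sub-table, with the closed-form probability ratio
as acceptance, a dememorisation burn-in, and the estimate averaged over
batches (defaults 10 000 / 100 batches / 5 000 iterations, the settings
used in the study; the reported standard error is the batch-mean standard
error, and the log-probability is re-synchronised once per batch to prevent
float drift). A seed is mandatory for the chain. Across loci, p-values of
informative loci are combined by Fisher's method (−2Σln p against
chi-square with 2k df); jointly monomorphic loci are flagged uninformative
and excluded, and a single informative locus passes its p through unchanged.

One published value resists reconstruction: the non-significant p (0.621)
for the 2017–19 vs 2010–14 Mora Romagnola comparison. The only allele
table derivable from the printed data is [[131, 553], [26, 122]], whose
exact p is 0.729 (enumeration; `scipy.stats.fisher_exact` agrees), so the
published figure evidently reflects the unprinted genotype-level data of
the earlier sample. The acceptance test states the published value and is
left failing with this documented explanation; the qualitative conclusion —
no significant differentiation between the two sampling windows — is
reproduced either way.

## Classical MDS

Breed relationships are embedded by Torgerson metric MDS: Euclidean
distances between concatenated per-locus allele-frequency vectors (absent
allele = 0), double-centred, eigendecomposed, coordinates scaled by the
square root of the eigenvalues. scikit-learn's MDS is SMACOF — a different
algorithm — so the classical procedure is coded directly on
`numpy.linalg.eigh`. Requesting more components than there are positive
eigenvalues truncates with a warning; the share of positive inertia
captured by the kept axes is reported. Sign convention: within each axis
the coordinate of largest absolute value is made positive, which fixes the
reflection ambiguity deterministically. Populations with identical
frequency vectors (the four EP-fixed cosmopolitan breeds in the shipped
panel) land on exactly the same point.

## Authentication statistics

For a comparison population, the mis-assignment error rate is
`ER = 1 − |δ|` per locus and `ERc = ER(MC1R) · ER(NR6A1)` combined. The
*MC1R* differential |δ| pools the target's two breed-specific alleles
(E+, e): since their frequency sums to one in the target after culling, the
pooled differential is `1 − (f(E+) + f(e))` in the comparison population,
and the implementation applies that premise exactly after validating the
target sum is within 0.002 of one (printed target rows sum to 1.001; using
the raw printed sum would shift every pooled δ by 0.001 away from the
published column). When the comparison population itself carries the target
alleles at summed frequency > 0.90 (wild boar, Duroc) the pooled
differential degenerates towards zero, so the per-allele mode —
`|f_t(a) − f_o(a)|` averaged over the two alleles, with the range also
reported — is selected for ER; both modes are always computed and reported.

The correct-assignment probability `PMR = 1 − Σ f(allowed genotype)` uses
*observed* genotype frequencies in the comparison population. When only
allele frequencies are available PMR is reported as unavailable rather than
imputed under Hardy–Weinberg (monomorphic breeds are the exception: fixation
determines the genotype table). The per-sample verdict is genotype
consistency with the standard's allowed set; a consistent verdict always
carries the caveat that Duroc meat (fixed for `e` and `T`) is
indistinguishable on this two-marker panel.

**Rounding.** Published-parity mode rounds input frequencies to three
decimals before any arithmetic, so a regenerated table is internally
consistent with a printed one (0.075 × 0.856 → 0.064); full-precision mode
is the default for new data. Reported values round half-up to three
decimals. One printed cell is ambiguous at the third decimal: the Duroc
per-allele δ (0.192 and 0.191 average to 0.1915) — its ER (0.809) is the
checked quantity. A second printed-value nuance: the recomputed target row's
`e` frequency 0.809 corresponds to `1 − 0.1915` rounded, not to 553/684 =
0.80848 (which rounds to 0.808); the panel ships the printed value.

## Synthetic data

`simulate_population` draws each animal's two alleles per locus
independently from the breed's frequency vector (single-generation
Hardy–Weinberg sampling; no pedigree, drift or generation overlap), with a
per-breed random stream derived from the mandatory seed via CRC32 so runs
are reproducible across processes. Phenotypes are drawn per age class;
default non-standard rates apply to young animals only (red coat 8.9 %,
non-standard ears 11 %, absent mane 9 %, the rates observed in the
phenotyping campaign) and adults are simulated as standard. What passing
tests on simulated data show is therefore calibration under the model's own
assumptions — HWE within breeds, independent loci, no genotyping error or
missingness structure; real herd data can violate all four, and the
compliance filter and exact tests make no use of the HWE assumption.

The printed-table fixtures are reconstructed in code (no data files): the
357-animal genotype table carries the published marginal counts with the
red-coated sow, the ED2/e boar and the two NR6A1 C-carrier sows placed
explicitly; the C-carriers are assumed `e/e` at *MC1R*, the single joint
assignment consistent with the recomputed retained-sample frequencies. The
13-population frequency panel and the 74-pig 2010–2014 allele counts
(26 E+/122 e) are embedded as printed.

## Problem sizes used in tests

The suite's stochastic checks use: 200 replicates of n = 300 for simulator
parameter recovery (three allele frequencies), 2 000 multinomial replicates
of n = 200 for the HWE type-I error calibration, 200 replicates of n = 200
per population for the null-theta check, and a 50-batch × 1 000-iteration
chain for MC-vs-enumeration agreement; the full 10 000/100/5 000 chain runs
in the acceptance test for the historical comparison. These sizes keep the
whole suite in the tens of seconds while leaving the binomial standard
errors well inside the asserted bounds.

## Known limitations

* Genotypes are unphased two-allele calls; no support for >2-digit GENEPOP
  allele codes, VCF or PLINK formats.
* The exact differentiation test covers two populations (the package's use
  case); the chain generalises to more rows but is not exposed for r > 2.
* PMR cannot be computed from allele-frequency-only panels for polymorphic
  comparison breeds (by design — see above).
* The authentication verdict is per-sample genotype consistency; mixtures
  and crossbred probability models are out of scope beyond the Duroc caveat.
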