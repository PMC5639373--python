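# Methods

This note documents the statistical models implemented in `hetmate`, the
choices made where the design was genuinely open, and what the synthetic
data do and do not establish about real field data.

## Genotype model and I/O

Genotypes are unordered pairs of positive integer allele codes; `0` is a
missing allele. Pairs are stored allele-ascending so equality is well
defined. Half-missing calls in input files are promoted to fully missing
with a logged warning — no statistic in this pipeline can use a single
allele copy. Monomorphic loci are retained by I/O and flagged; downstream
statistics exclude them (they carry no information, and their
`E_l = 0` would otherwise silently distort HL denominators).

Allele frequencies are estimated by gene counting over non-missing calls.
For relatedness, the power sums a₂ = Σp², a₃ = Σp³, a₄ = Σp⁴ are by
default bias-corrected using falling factorials of the allele counts in
the `2n` sampled gene copies (`corrected=True`); frequencies supplied as
exact population values (e.g. simulation truth) skip the correction.

## Homozygosity by locus

`HL = Σ_hom E_l / (Σ_hom E_l + Σ_het E_l)` over an individual's typed
polymorphic loci, with plug-in `E_l = 1 − Σ p̂²` (the conventional form for
this index; the unbiased variant is available via `corrected=True` but is
not the default). `het = 1 − HL` exactly. Individuals with fewer than
`min_loci` usable loci (default 10 of 17, i.e. ~60% typed — a common
convention, logged in results) or a zero denominator are flagged with no
value rather than silently imputed.

The split-half heterozygosity correlation partitions loci at random into
halves of ⌊L/2⌋ and ⌈L/2⌉, computes per-individual het on each half and
records the Pearson correlation across individuals; 1000 splits by
default. Splits with zero het variance in a half are recorded as
undefined and excluded from the summary with their count reported. The
correlation is driven by identity disequilibrium: with uniform inbreeding
it is near zero even when the panel is perfectly adequate, so a low value
does not by itself condemn a panel — the quantity is reported with its
2.5/97.5% quantiles and left to interpretation.

## Pairwise relatedness

The estimator is a method-of-moments estimator of the two-gene and
four-gene IBD coefficients (φ, Δ) with `r = φ/2 + Δ`. At each locus the
dyad's genotypes fall into one of four identity-by-state categories
(identical genotypes; homozygote vs heterozygote carrying its allele; two
heterozygotes sharing one allele; no shared allele). For outbred
individuals the category probabilities are linear in (φ, Δ) with
coefficients that are polynomials in a₂, a₃, a₄; the expressions are
derived by direct enumeration of allele draws and verified against Monte
Carlo simulation in the test suite. Numerically, category indicators and
coefficients are averaged across a dyad's usable loci with weights
`1/(2a₂ − a₄)` (down-weighting loci where random dyads already look
similar), and the resulting over-determined 3×2 linear system is solved by
least squares — a linear-unbiased combination under the model. Estimates
are deliberately not clamped to [−1, 1]; out-of-range values are flagged
so that dyad-class averages remain unbiased. Dyads with no usable shared
locus are returned as NaN with `n_loci = 0`.

Validation is by pedigree recovery: dyads built by explicit gamete
transmission (clone, parent-offspring, full-sib, half-sib, unrelated; 20
loci, 8 equifrequent alleles, frequencies re-estimated from the sample)
give class means within ±0.05 of 1 / 0.5 / 0.5 / 0.25 / 0, and the
sampling SD shrinks as loci increase from 5 to 20. A Queller-Goodnight
regression estimator is included purely as an independent cross-check
route in the tests; it is never the default.

## Offspring heterozygosity

Offspring are simulated by free Mendelian transmission: one uniformly
chosen allele per parent per locus, independent across loci and offspring;
no mutation, no linkage. Loci missing in either parent are dropped for
that dyad, not imputed. The Monte-Carlo protocol averages the mean HL of
100 simulated offspring over 1000 iterations (means of iteration means;
the reported `mc_se` is the SD of iteration means over √iterations).

Because all offspring of a dyad are typed on the same locus set, HL's
denominator `Σ E_l` is constant and the exact expectation factorises:
`E[HL] = Σ E_l·h_l / Σ E_l`, where `h_l` is the probability the offspring
is homozygous at locus *l* (the number of equal paternal/maternal allele
picks over 4). `expected_offspring_hl_exact` returns this closed form; a
brute-force 4^L enumeration in the tests confirms it to 1e-12. Offspring
HL is evaluated under the parental population's allele frequencies, not
frequencies re-estimated from simulated offspring, matching its use as a
dyad-level covariate.

## Resampling tests

*Assortment.* Observed statistic: Pearson (default; Spearman available)
correlation of female and male trait values over pairs. Null: permute the
females among pairs, within year when year labels exist (the within-year
choice mirrors the relatedness randomization design; the marginal trait
multisets are asserted unchanged on every run). Two-sided add-one p-value
`(1 + #{|T_null| ≥ |T_obs|})/(n_perm + 1)` — strictly valid at any
`n_perm`; default 10 000 permutations.

*Relatedness randomization.* Observed statistic: mean pair relatedness.
Null replicate: an independent random bijection of each year's females to
that year's males; 100 000 iterations by default; plain percentile 95%
interval (not BCa). Cross-year pairings never occur.

*Similarity preference.* Statistic: Pearson correlation across all
(trial, stimulus) observations between the association proportion and
`s = −|het_focal − het_stimulus|` (invariant to shifting all het values).
Null: permute the six proportions within each trial — the design's only
exchangeability, since proportions are constrained to sum to one per
trial. This permutation test is the package's inference for
similarity preference; a mixed-model treatment of the same question is
out of scope here.

*Paternity exclusion.* Per locus, the offspring's candidate paternal
alleles are its alleles minus one attributable to the mother; when the
mother shares both (or, degenerately, neither — a mother-offspring
mismatch, treated conservatively), both offspring alleles remain
candidates. A locus mismatches when the candidate sire carries neither
candidate allele; exclusion requires ≥ 2 mismatching loci by default
because single-locus mismatches are commonly genotyping artefacts. The
threshold is configurable; likelihood-based assignment is out of scope.

## Repeatability

One-way ANOVA intraclass correlation over focal-stimulus combinations
with raw association durations as the response:
`r = (MS_among − MS_within)/(MS_among + (n0 − 1) MS_within)`,
`n0 = (N − Σk_i²/N)/(g − 1)` for unbalanced groups. Negative estimates are
reported as-is with a flag. The quoted uncertainty is a bootstrap SE over
focal-stimulus combinations (1000 resamples, degenerate resamples
skipped) and is labelled as such — it is not a parametric SE. Repeated
group-A tests: both A tests enter the repeatability ANOVA, but only the
second enters the preference dataset, keeping one test per focal-stimulus
dyad and avoiding first-exposure habituation effects.

## Synthetic data

The generators emulate the study conditions: 17 polymorphic loci with 8
alleles each (symmetric-Dirichlet frequencies, concentration 1; `None`
gives exactly equifrequent alleles), ~300 diploid individuals, HWE with
optional inbreeding (autozygosity with probability F per locus; F may
vary across individuals to induce identity disequilibrium), breeding
pairs over two year labels with a rank-matching scheme whose realised
female-male het correlation approximates `assortment_rho`, ABCA
six-choice trial blocks whose Dirichlet durations load on heterozygosity
similarity through `exp(−strength·|Δhet|)` with ~13% all-zero trials
(echoing the observed exclusion fraction), and cross-fostered broods with
a 10% extra-pair siring rate, rotated among same-hatch-day brood triplets
so no chick stays with its biological parents. Sexes alternate
deterministically — balanced by construction and irrelevant to the
statistics. Every generator is a pure function of (config, seed) with a
fixed substream per generator; outputs are bitwise reproducible.

What the synthetic data do **not** model: genotyping error and null
alleles (so paternity false-exclusion rates on real data will exceed the
simulated ~0%), linkage and departures from HWE other than inbreeding,
spatial or social structure in mate availability, movement mechanics of
the choice chamber (durations are Dirichlet draws, not a behavioural
model), and survival/multi-season dynamics. Passing tests therefore
establish the correctness and calibration of the estimators and tests
under their stated assumptions, not the field conclusions themselves.

## Problem sizes and numerics

Replicated experiments use desk-scale sizes chosen once: 500 dyads per
pedigree class; 200 dyads for the Monte-Carlo/exact offspring check (100
offspring × 200 iterations); 1000 replicate datasets of 70 pairs at 999
permutations for test calibration; 500 replicates at 2000 iterations for
randomization coverage; 60-trial sets at 199 permutations for the
similarity-test calibration with a power grid at strengths 0/0.6/1.2/2.5;
2000 trios for exclusion recovery. Default analysis settings remain at
the full protocol (10 000 permutations, 100 000 iterations, 100×1000
offspring simulation). Numerical details: permutation p-value comparisons
use a 1e-12 slack to avoid float-equality artefacts; the randomization
interval's inside check uses the same slack; least-squares systems with
near-singular normal matrices (no usable loci) return NaN rather than a
value; iteration means with `n_iterations = 1` report an undefined SE.

## Known limitations

The relatedness moment system is solved by ordinary least squares over
the three category equations rather than the original variance-optimal
closed-form combination, a deliberate simplification that preserves
unbiasedness but not full efficiency; with 17–20 loci the pedigree
recovery bias is well inside ±0.05 and the precision loss is immaterial
at this panel size. HL's `min_loci` default and the exclusion threshold
of 2 mismatching loci are conventions, not estimates; both are
configurable and echoed into run manifests. The bootstrap repeatability
SE treats focal-stimulus combinations as exchangeable, which ignores the
sharing of focals across combinations.
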