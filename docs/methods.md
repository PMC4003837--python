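# Methods

## Data model and notation

Variants are identified by their coding-sequence change (`c.478C>T`) and,
when applicable, protein change (`p.R160W`), on 1-based coding coordinates
(NM_002386.3 numbering for MC1R).  The affected codon is
`ceil(position / 3)` of the first affected nucleotide; for substitutions
with protein notation the protein residue number is authoritative, and a
disagreement between the two routes is flagged on the record
(`codon_mismatch`) instead of being repaired.  The packaged count table
contains exactly one such flagged row (`c.417G>A` / `p.V140M`, whose
printed cDNA position falls in codon 139): the transcription preserves the
printed strings and trusts the protein change for domain placement.
Insertions/deletions carry no protein notation; their codon comes from the
cDNA position and their consequence from the length change (non-multiple
of three → frameshift).  Two typographic artefacts of printed tables are
normalised on input: `<` for `>` and a space before `ins`/`del`.

## Classification rules

A variant is assigned exactly one class, in precedence order:

1. **R** — protein change in the RHC allele list (default D84E, R142H,
   R151C, R160W, D294H).  The list is an input, not an inference, and
   beats frequency: D84E sits below the rarity threshold (36/4000) yet is R.
2. **synonymous_frequent / synonymous_rare** — synonymous changes, split
   at the rarity threshold.  Synonymous variants are never D/nD members
   but do count in pooled "all r" burden and in the reference definition.
3. **frequent_r** — combined allele frequency ≥ 1%.
4. **rare_r_D / rare_r_nD** — below 1%: damaging when truncating
   (nonsense/frameshift, always) or when the in-silico consensus flag is
   set (≥ 1 of 3 tools; the packaged table carries the pre-aggregated
   flag); non-damaging when the flag is explicitly negative.  A rare
   nonsynonymous variant with no prediction and no truncation raises an
   error rather than defaulting to nD.

The rarity denominator defaults to the **combined** cohorts (4000
chromosomes here) because that choice uniquely reproduces the transcribed
rare/frequent flags (R142H at 42/4000 = 1.05% is frequent; T314T is
frequent; every flagged-rare row is < 40 alleles).  Threshold and
denominator are configurable.

## Association statistics

Every comparison is a 2×2 allele table against the **reference
haplotypes**: chromosomes carrying no nonsynonymous variant (wild-type or
synonymous-only), 936 in patients and 976 in controls in the packaged
cohort.  Reference counts are an *input* in count-mode and are recomputed
from subject-level data in simulation mode; the two conventions are never
mixed, and pooled counts are never subtracted from chromosome totals,
because haplotypes can carry more than one variant (the packaged totals
are visibly non-additive: 2262 − 500 − 980 ≠ 936).

- **Odds ratio**: cross-product `(a·d)/(b·c)`; a zero in `b` or `c`
  triggers the Haldane–Anscombe +0.5 correction and is flagged.
- **Confidence interval**: Woolf — `exp(ln OR ± z · √(1/a+1/b+1/c+1/d))`,
  default level 95%.  The published intervals this package's fixtures
  derive from were produced by exact-CI software: for large-count rows
  Woolf agrees to ±0.03, but for small-count rows (D, nD, I155T, R142H,
  D84E) the printed intervals are wider, tracking exact conditional
  intervals (differences up to ≈0.25 on the upper endpoint).  Exact
  conditional/mid-p intervals are deliberately out of scope; the Woolf
  choice is documented here and the disagreement is surfaced by the test
  suite rather than hidden.
- **p-value**: two-sided Fisher exact test (sum of hypergeometric
  probabilities ≤ the observed table's, margins fixed), via
  `scipy.stats.fisher_exact`, floored at the smallest positive float.  The
  test suite checks it against an exact-integer enumeration oracle over
  every 2×2 table with total ≤ 40.
- **PAF**: `p(OR − 1)/(p(OR − 1) + 1)` with `p` the *control allele
  frequency* (count / control chromosomes) — back-substitution shows this,
  not carrier prevalence, reproduces the published pooled values.
  Reported percentages use the OR rounded to two decimals, the precision
  at which odds ratios are printed; with unrounded ORs the pooled-r PAF
  moves from 16.6% to 16.5%, so both conventions are exposed.  OR < 1
  yields a negative PAF flagged as preventive; OR = 0 (no case alleles) is
  allowed and gives −p/(1−p).
- No multiple-testing correction by default (single-cohort design with
  interdependent tests); Bonferroni/FDR helpers exist but are opt-in.

### Reconciliations in the packaged fixtures

Summation over the transcribed count table reproduces every published
pooled count only under these memberships, which are therefore the
defaults: "all r" includes synonymous variants (980/678); "rare r" is rare
nonsynonymous plus indels, excluding synonymous (57/31); per-domain pools
include every consequence class and indels (intracellular-2 = 403/153,
transmembrane-7 = 95/40).

One variant needs a documented override: **G104S** carries a positive
damaging flag in the transcribed table, but the published pooled D/nD
counts (48/21 and 9/10) and the extracellular-1 domain tally only
reconcile with G104S counted as nD.  The rule-based classifier follows the
flag (40 rare-damaging variants, matching the published census); the
published-table reproduction applies the single-variant override
(`pipeline.PAPER_CLASS_OVERRIDES`), which callers can disable.

Known non-reconciling printed values, asserted nowhere as goldens: the
D84E odds ratio (prints 1.85; cross-product gives 1.8449), the individual
PAFs of R151C, R160W, D84E and V60L (printed 7.4/5.7/0.8/6.5 versus
back-computed 7.6/5.4/0.6/6.4), and the domain-clustering significance
bound (printed < 0.0001; the exact test on the reconstructed 40/23/4/18
table gives 3.8×10⁻⁴, a chi-square 2.5×10⁻⁴).  The clustering fractions
themselves (63% vs 18%) reproduce exactly.

## Domain analysis

The 15-domain table partitions residues 1..317 contiguously (N-terminus
M1–E37 through C-terminus F300–W317); assignment is by binary search and
out-of-range codons are errors.  Per-domain burden pools *all* variant
alleles whose codon falls in the domain and runs the same association
bundle; variant-free domains return a flagged empty result.  The
clustering statistic compares the fractions of D and nD alleles falling in
a domain set (default Ic2, TM2, TM5, TM7 — the domains that also harbour R
alleles) with a Fisher test on the in/out × D/nD table.  The transcribed
per-domain D/nD tallies exclude the three indels (totals 63 D / 22 nD) and
embed the G104S reassignment; a recompute-from-records mode exists and its
cell-level disagreements with the transcription are asserted in the tests.

## Adjusted analysis

Logistic regression of case status on a variant-class term plus the four
ordinal pigmentation covariates (hair colour, eye colour, Fitzpatrick skin
type I–IV, nevus count in four bands).  Covariates enter as single ordinal
integer scores — matching the one-OR-per-covariate shape of published
adjusted tables, whose level codings are not stated — with dummy coding
available by recoding columns upstream.  The genetic term defaults to
carriage (≥ 1 allele of the class) with allele-dosage optional.  The fit is
IRLS with tolerance 1e-8 on the coefficient change and at most 50
iterations; Wald intervals are `exp(β ± z·SE)`.  Complete separation is
detected (diverging coefficients with boundary fitted probabilities) and
raised as an explicit error.  Missing covariates drop the subject
(complete-case) with the count reported.  The published adjusted odds
ratios cannot be reproduced because individual-level data are not
published; the machinery is validated by brute-force likelihood
optimisation on tiny datasets, an independent-library cross-check, and
parameter-recovery simulations (below).  Age at diagnosis between carriers
and non-carriers is compared with a Welch unequal-variance test (the
source analysis names no test); two degenerate identical groups return
p = 1 by convention.

## Synthetic cohorts

The generator emulates the study design, not MC1R population genetics:
diploid subjects, haplotypes drawn independently (no linkage) from a
catalog of class-labelled alleles at specified control-population
frequencies, **at most one nonsynonymous variant per haplotype** — the
same idealisation the reference-haplotype count implies.  Disease status
follows a logistic model whose class coefficients are ln(class OR), with
per-haplotype (dosage) effects by default because the association
estimator counts haplotypes; carriage-coded generation is available and is
what the adjusted-model recovery tests use so generation matches the
analysis coding.  Baseline population prevalence defaults to 10% — high
for melanoma, chosen to keep rejection sampling (drawing population
subjects until the exact case/control quotas fill) efficient; because
sampling is outcome-dependent, class effect estimates are unaffected by
the intercept.  The four covariates are drawn from ordinal level
probabilities, independent of genotype by default, with an optional
exponential-tilt correlation knob and optional direct covariate effects on
disease for confounding experiments.  Cases receive a diagnosis age
(normal, mean 54, SD 12, truncated to 15–95) with per-class mean
overrides (the example spec gives damaging-variant carriers mean 45).

What passing calibration shows — and does not.  Default study conditions
are the published cohort sizes (1131/869) and the published pooled class
frequencies/odds ratios (R 0.11/2.66, frequent r 0.39/1.51, D 0.012/2.38,
nD 0.006/1.0).  Under these conditions the estimators recover generating
ORs within a few percent in the median, the exact test holds its size, and
Wald intervals cover at near-nominal rates; none of this probes linkage
between variants, compound haplotypes (a multi-variant-haplotype mode
exists for documentation experiments), population stratification, or
genotyping error, all absent from the generator.  Rare classes carry only
dozens of alleles at these sizes, so single-replicate rare-class ORs are
intrinsically noisy (log-OR sampling SD ≈ 0.2–0.3); calibration statements
about them are median- or mean-based by necessity.

## Problem sizes used by the test suite

Deterministic count-mode checks run on the full 79-variant fixture.
Stochastic calibrations use: 200 seeds at the study's own size for median
OR recovery; 200 seeds of 2500/2500 cohorts for Wald coverage of
β = ln(2.22) (acceptance band 0.905–0.995, ±3 binomial SD around the
nominal 95%); 10,000 replicates of 100/100 cohorts for the size of the
exact test (observed ≈ 0.036 against the ≤ 0.055 bound — exact tests are
conservative on discrete small tables); and an exhaustive Fisher-vs-
enumeration sweep of all 135k tables with total ≤ 40.

## Numerical choices

Log-likelihoods use `logaddexp`; IRLS weights are floored at 1e-12;
Fisher p-values are floored at the smallest positive double so log-scale
reporting never sees zero; Haldane corrections are always flagged in the
result object; domain lookup is O(log n) bisection; all random streams are
`numpy` `default_rng` seeded explicitly, and a fixed seed makes cohort
generation byte-identical.
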