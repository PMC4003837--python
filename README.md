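# mc1rburden

Class-based burden association of **MC1R** coding variants in melanoma
case-control data.

MC1R, the melanocortin-1 receptor, is a highly polymorphic seven-pass
G-protein-coupled receptor central to the eumelanin/pheomelanin switch.
Its coding variants are conventionally split into red-hair-colour **R**
alleles (here D84E, R142H, R151C, R160W, D294H), frequent non-RHC **r**
alleles (≥ 1% allele frequency), and rare r alleles subdivided by in-silico
consensus into predicted-damaging **D** (nonsense and frameshift variants
are always D) and non-damaging **nD**.  This package implements the full
allele-level analysis such a study runs, for epidemiologists and statistical
geneticists who want every stage reproducible from plain count tables:

- parsing of cDNA/protein change notation, consequence typing, and a
  variant census (`variants`);
- rule-based class assignment under a configurable rarity threshold and
  prediction-vote rule (`classify`);
- association of each variant or pooled class against the **reference
  haplotypes** — chromosomes carrying no nonsynonymous variant — via the
  cross-product odds ratio, Woolf confidence interval, two-sided Fisher
  exact test, and the population attributable fraction
  `PAF = p(OR − 1) / (p(OR − 1) + 1)` with `p` the control-side allele
  frequency (`association`);
- mapping of variants onto the receptor's 15 domains, per-domain pooled
  burden, and a D-vs-nD domain-set clustering test (`domains`);
- covariate-adjusted logistic regression (IRLS, Wald intervals) of case
  status on class carriage plus four ordinal pigmentation covariates
  (`multivariate`);
- a synthetic diploid case-control cohort generator with class-labelled
  alleles at specified frequencies and odds ratios, used to calibrate every
  estimator without any external data (`simulate`).

The packaged fixtures transcribe the count tables of a French case-control
resequencing study (1131 melanoma patients / 869 controls; 2262 / 1738
chromosomes; 936 / 976 reference haplotypes), so the entire published
analysis replays offline.

## Worked example

```sh
$ mc1rburden classify
79 variants (53 missense, 2 nonsense, 3 frameshift, 21 synonymous)
rare: 69 (damaging 40, novel 25)

$ mc1rburden run-paper --out reports
All R variants: OR 2.66, PAF 15.8%
Intracellular 2: OR 2.75
reports written to reports
```

The census line is the variant inventory: 79 distinct coding variants, of
which 69 are rare (< 1% combined allele frequency, non-RHC), 40 of those
predicted damaging and 25 previously unreported.  The association report
(`reports/association_report.tsv`) starts:

```
label           case_alleles  control_alleles  maf_cases  maf_controls  odds_ratio  ci_low  ci_high  p         paf_percent
All R variants  500           196              0.221      0.1128        2.66        2.2     3.21     6.05e-26  15.8
```

Reading: the five R alleles occur on 500 of 2262 patient chromosomes versus
196 of 1738 control chromosomes; against the reference haplotypes that is an
odds ratio of 2.66 (Woolf 95% CI 2.20–3.21), and if the association were
causal, 15.8% of melanoma in this population would be attributable to R
alleles.  Pooled r alleles give OR 1.51 with a nearly identical PAF (16.6%),
and the rare damaging class reaches OR 2.38 — as strong as the R alleles.
The domain report shows the two highest-burden regions, intracellular
loop 2 (OR 2.75) and transmembrane helix 7 (OR 2.48), and

```sh
$ mc1rburden domains | tail -1
set {Ic2,TM2,TM5,TM7}: D 63% vs nD 18%, p 0.00038
```

shows that 63% of damaging rare-variant alleles but only 18% of
non-damaging ones fall in the four domains that also harbour R alleles.

Synthetic cohorts for calibration or power work:

```sh
mc1rburden simulate --seed 17 --out subjects.tsv      # packaged example spec
mc1rburden multivariate --subjects subjects.tsv --term R
```

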