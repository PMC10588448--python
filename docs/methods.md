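# Methods

## Model and procedure

The package implements a gene-collapsing (burden) comparison of rare
germline alleles in a sequenced case cohort against a public population
control given only as per-variant allele counts (AC) and allele numbers
(AN). For a gene, subset and rarity-tier group, the collapsed data form a
2×2 allele-count table

|          | alt alleles | total/comparator |
|----------|-------------|------------------|
| cases    | a           | b                |
| controls | c           | d                |

and inference conditions on all margins: under the null of no association,
the case alt count X follows the central hypergeometric distribution; under
an odds ratio ψ it follows Fisher's noncentral hypergeometric distribution.

- **One-sided p (enrichment):** P(X ≥ a) under ψ = 1.
- **Two-sided p:** the point-probability summation convention of R's
  `fisher.test`: Σ P(X = x) over support points with
  P(X = x) ≤ P(X = a)·(1 + 10⁻⁷).
- **Odds ratio:** the conditional MLE, i.e. the ψ solving E_ψ[X] = a. This is
  what `fisher.test` reports and is distinguishable in published tables from
  the cross-product ratio a·d/(b·c) (1.6837 vs 1.6857 at gnomAD-scale
  margins); both are emitted.
- **Adjustment:** Benjamini–Hochberg step-up with an explicit family size m
  that may exceed the number of supplied p-values
  (adjusted_i = min_{j ≥ i} p_(j)·m/j, capped at 1). The family is per gene
  across subsets × tier groups — size 8 for a four-subset run. Bonferroni
  (min(1, p·m)) is available behind a flag. Published reports in this
  problem area sometimes describe the adjustment as Bonferroni while the
  tabulated values are BH; the package defaults to BH because that is what
  reproduces the reference table digit for digit.

### 2×2 construction

Two constructions are supported. `alt_vs_total` (default) places the total
allele number, not total − alt, in the second column. This is not the
textbook contingency table, but it is the construction under which the
reference report's printed p-values and conditional ORs reproduce exactly,
and with alt counts three orders of magnitude below the denominators the
difference is confined to the fourth significant digit. `alt_vs_ref` gives
the classical construction. The choice is a per-run policy recorded in the
run manifest.

## Filtering and classification

Genotype-level QC (defaults; all configurable): allelic balance strictly
> 0.2 on any non-reference call; GQ strictly > 20; heterozygous VAF inside
the inclusive [0.20, 0.80] window; alt reads ≥ 10 (SNV) / ≥ 7 (indel); VAF
is computed from AD only. The balance floor and the het VAF window are kept
as separate rules — the floor applies to all non-reference calls, the window
to heterozygotes only — because both criteria exist independently in the
filtering scheme being modeled. Hom-alt calls are exempt from the window.
Site-level: missingness strictly < 25% of samples. MNVs are grouped with
indels for the alt-read rule.

Candidate variants: consequence ∈ {missense, frameshift indel, stop gain,
splice}, control AF strictly < 0.5%, and for missense a CADD Phred strictly
> 15. Missense with no CADD score is excluded (the filter retains variants
*with* a qualifying score) and logged.

Rarity tiers partition control AF with strict upper bounds: novel (exactly
0, including variants absent from the control table), ultra-rare
(< 0.005%), very rare (< 0.05%), rare (< 0.1%), low-frequency (< 0.5%).
The very-rare bound has no established published value; 0.05% is this
package's convention (roughly the geometric midpoint of its neighbours) and
no statistic depends on it — the tested tier groups are ultra-rare + novel
and < 0.1%, both externally defined.

Stability calls for missense variants use the ingested folding free-energy
change: destabilizing when ΔΔG ≥ +1.5 kcal/mol, stabilizing when
≤ −1.5 kcal/mol (a ~12-fold shift of the folded:unfolded equilibrium).
The bound is inclusive: reference variant sets count changes tabulated at
exactly 1.5 among the significant ones, so an exclusive reading would
contradict the data the rule describes.

## Denominator (AN) accounting

Case allele totals in published collapsed tables are slightly below 2N
(e.g. 11,951 for 5,993 cases), implying per-site allele-number accounting
rather than a fixed 2N. The exact rule is not stated anywhere we can verify,
so it is a policy: the default (`site_mean`) takes the rounded mean called
allele number — 2 × non-missing subset samples — across the gene's sites;
`site_median` and `2n` are alternatives. Control totals analogously use the
mean AN across the gene's qualifying control sites. Statistics computed
from externally supplied counts (the packaged reference table, the
acceptance script) are independent of this policy.

## Numerical choices

All tail sums are computed in log space: log pmf values come from a cached
array of log-factorials (gammaln(n+1)), grown on demand, and are combined
with a single max-shift exponentiation. Margins of ~2.7×10⁵ are far beyond
naive factorials but trivial in log space; agreement with exact integer
enumeration is within 10⁻¹² absolute for every table with total ≤ 60
(tested exhaustively). A whole-support tail returns exactly 1. The
conditional MLE is found by bisection on log ψ (interval expanded until it
brackets, ≤ 200 iterations) to |E_ψ[X] − a| < 10⁻¹⁰; at the support
boundaries the estimate is 0 or +∞ by convention, and a degenerate
single-point support returns 1. The two-sided fuzz 1 + 10⁻⁷ matches the R
convention and is part of the statistic's definition here.

## Synthetic cohorts

`simulate_cohort` draws, per site: a control AF from a weighted spectrum
(default point masses at 0, 2.5×10⁻⁵, 2×10⁻⁴ and 8×10⁻⁴, equally weighted,
populating every tier the statistics use); a control AC = round(AF·AN); and
independent heterozygous case carriers with probability 2·AF·λ_gene
(a configuration implying probability > 1 is rejected). Defaults — 500
cases, control AN 20,000, six genes of eight sites — are the scaled-down
study conditions used for calibration testing; under them a gene at λ = 10
carries ≈ 20 expected carriers. Carrier read support is Poisson-depth
(mean 60, floored at 24) with the alt count clamped into the central
[0.3, 0.7] VAF band, so a clean carrier can never fail default QC by
sampling accident; carriers selected by `qc_noise` are conversely
guaranteed to fail (GQ ≤ 20, or VAF ≈ 0.1). Non-carrier genotypes go
missing with `missing_rate`; carriers are never masked, so the truth record
stays exact. Samples are assigned disjointly to three strata (probabilities
0.532/0.304/0.164, proportional to the hematologic/solid/CNS mix of the
modeled cohort) alongside the all-sample stratum. Replicate seeds derive
from the master seed via a splitmix64-style scrambler, documented so any
implementation can reproduce the stream.

What the generator does *not* emulate: linkage/haplotype structure,
ancestry stratification between cases and controls, relatedness, base-level
sequencing error, and per-site control-AN variation (constant by default so
denominator-policy effects stay visible). Passing calibration therefore
demonstrates correctness of the pipeline and the exact inference under
independent sampling — not robustness to confounding, which a real analysis
must address upstream.

Calibration (200 null replicates at the default conditions) shows per-gene
family-adjusted rejection rates well under the nominal 0.05 — Fisher's exact
test is conservative at these counts — with power ≥ 0.8 at λ = 10 and a mean
conditional-MLE OR monotone in λ over {1, 3, 10}.

## Known limitations

- Sex chromosomes are treated as diploid; no ploidy model (the genes this
  was built around are autosomal).
- Indel keys are matched exactly; inputs are assumed left-normalized
  upstream, and no liftover is provided.
- Confidence intervals for the conditional OR are not computed.
- Overlapping cohort subsets are tested as given, with no correction for a
  sample appearing in several strata.
- The two-sided FDR column of the packaged reference table is not
  recomputable from its printed rows alone (the adjustment family included
  unprinted tests), and is excluded from the reproduction diff.
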