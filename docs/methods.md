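# Methods

This note documents the models, statistical procedures and design choices
behind `koscan`, in the spirit of a package methods appendix: what is
computed, under which assumptions, and what a passing test does and does
not establish.

## Target-site model

A target site is a 20-nt SpCas9 protospacer immediately 5' of an NGG PAM
on the targeted strand. Coordinates are 0-based, half-open, reported on the
forward strand of the reference so that site lists are valid BED intervals;
minus-strand sites store protospacer and PAM as 5'→3' strings on the minus
strand (the forward strand then shows `CCN` immediately 5' of the
protospacer interval). The scanner enumerates both strands, skips any
window containing an ambiguity code (assemblies contain gaps; a site
overlapping an N is not designable), and rejects non-IUPAC characters
outright.

The **seed** is the 12 PAM-proximal protospacer bases, positions −1
(adjacent to the PAM) through −12; the full protospacer spans −1..−20. The
seed dominates target recognition, so GC and motif statistics default to
it. The PAM is never included in any GC computation. Guides transcribed in
vitro from a T7 promoter need one or two leading G bases, which inflates G
at positions −20/−19 for design reasons unrelated to cleavage efficiency;
those positions are flagged `t7_biased` in composition output and can be
excluded from testing.

## Cohort statistics

Sites tested in founders carry a `positive` (mutations detected) or
`negative` label. The comparisons and their tests:

| quantity | test | family for BH |
| --- | --- | --- |
| per-site seed GC% between cohorts | Mann–Whitney U, two-sided | — |
| success rate vs seed GC count (13 bins) | Cochran–Armitage trend (count-weighted) + unweighted Pearson r over populated bins | — |
| per-position base composition (20 × 4 cells) | Fisher exact on each 2×2 (base vs not-base × cohort) | all emitted cells |
| seed k-mer motif fractions (k = 2, 3; literal or S/W-collapsed alphabet) | Mann–Whitney U on per-site window fractions (aggregated mode) or Fisher per window position | all motifs (× positions) in the call |
| PAM usage (AGG/CGG/GGG/TGG) | chi-square homogeneity on the 2×4 table | — |

Rationale: exact or rank-based nonparametric defaults for count-scale data;
nothing assumes normality of GC fractions. The Cochran–Armitage statistic
is implemented from its closed form (no canonical scipy/statsmodels
version exists for the 2×k score layout) and is validated against a seeded
Monte Carlo permutation null in the test suite. Degenerate inputs are
defined, not errors: a flat rate curve has Pearson r = 0 and trend p = 1;
a zero-variance GC comparison has p = 1; enrichment ratios with a zero
denominator are reported as NaN (undefined), never infinity.

"Seed GC content > 50%" means a GC count of at least 7 of 12 — 6/12 is
exactly half, not more than half.

Benjamini–Hochberg is applied within each emitted family; q-values are a
monotone step-up transform of the p-values, so shrinking a family (e.g.
excluding T7-biased positions) can only keep or raise significance
thresholds, never silently mix families.

## Allele model

Each mutant allele is explained by a **single contiguous lesion**: the
maximal common prefix of (wt, mut) is taken first, then the maximal common
suffix of the remainders subject to |prefix| + |suffix| ≤ min(|wt|, |mut|).
Any feasible (prefix, suffix) split is dominated by the maximal ones, so
this greedy order attains the minimal single-locus edit; prefix-first makes
the breakpoint deterministic (in a repeat run it lands at the 3' end of the
run). A multi-locus edit that a single event cannot explain surfaces as one
delins spanning the whole unexplained region — it is not decomposed.

Classes: `none` (wt == mut), `deletion`, `insertion`, `delins` (both
segments non-empty), and `big_indel` for deletions longer than 200 bp (the
intended product of paired-gRNA designs; threshold configurable). Frame
effect is pure arithmetic: a coding lesion is `in_frame` iff its net length
change is divisible by 3; premature stop codons, splice sites and
regulatory effects are not evaluated. Cohort summaries count big indels and
then exclude them (and `none` calls) from the class and frame
denominators; percentages are rounded half-away-from-zero to one decimal,
the convention used for every reported rate in the package.

## Synthetic campaign generator

The generator emulates the two tables a real campaign would deposit:

* **Sites.** 1333 genes, a shifted-geometric number of tested guides per
  gene with mean 2277/1333 (so a default campaign tests ≈ 2277 guides).
  Protospacer bases are i.i.d. with GC probability 0.509 and one forced
  leading G (T7 transcription), giving expected seed GC of 50.9% and full
  protospacer GC of ≈ 53.4%. The success label follows a logistic model on
  the centered seed GC count, `P(positive) = σ(β₀ + β₁(g − 6))`. β₁
  defaults to 0.1588, solved (by binomial expectation and root finding) so
  the expected positive/negative seed-GC gap is 3.9 percentage points; β₀
  is solved so the marginal positive rate is 1086/2277 ≈ 0.477. The
  logistic link encodes a monotone GC–success relationship; it is a
  modelling device, not a mechanistic claim.
* **Alleles.** Lesion class from the mixture (0.614, 0.111, 0.275) over
  deletion/insertion/delins, with a 24/954 probability of a big indel
  (> 200 bp, two-gRNA) drawn first. Sizes are shifted-geometric — the
  maximum-entropy distribution on positive integers given a mean — with
  means 10.9 (deletion), 6.4 (insertion), and 9.0/10.3 (delins deletion /
  insertion). Lesions are applied at the centre of a 600-nt random context.
  Delins draws are **canonicalised**: the inserted segment is forced to
  differ from the deleted segment at both boundary bases. Without this,
  ~11% of delins draws would be non-minimal parses (an insertion starting
  with the deleted segment's first base is indistinguishable from a
  smaller lesion), and "truth" would be ill-defined rather than the
  classifier wrong. With it, class, segment sizes and net length change
  are recovered exactly by construction; size distributions are unchanged.
* **Campaign.** Germline transmission per mutated gene (p = 636/1029),
  alleles per germline gene (shifted geometric, mean 1039/636), F2
  advancement per allele (703/1039) and early-phenotype detection per
  screened allele (47/701) are independent Bernoulli/geometric draws, and
  the returned counts are independent tallies of the generated tables.

What the generator does **not** emulate: microhomology-driven repair
outcomes, position of lesions relative to cut sites in real genes, linkage
between guide features and allele spectra, mosaic founders, or any
off-target events. A green test on synthetic data therefore establishes
correctness of the bookkeeping and statistics under the stated model, not
biological realism of the sequences themselves.

## Numerical conventions

* Percentages: half-away-from-zero, one decimal (`percentage(1029, 1333)`
  → 77.2). Two published-style roundings (47.8% for 1086/2277, 58.9% for
  703/1191) are inconsistent with their own fractions; the package reports
  the recomputed values (47.7, 59.0).
* Empty GC bins have undefined (NaN) positive rate and are excluded from
  the Pearson correlation; bins below a configurable minimum count can be
  excluded too (default: include all).
* All randomness flows through one `numpy` Generator seeded from the
  config, so identical configs produce byte-identical tables.
* Fisher p-values come from `scipy.stats.fisher_exact` and are
  property-tested against direct hypergeometric tail enumeration for all
  margins ≤ 30.

## Known limitations

* The founder-screen definition of an "efficient" guide (what mutation
  fraction counts as positive) is taken as given in the input labels; no
  detection-threshold model is fitted.
* The diff cannot separate two independent lesions on one allele; they are
  reported as a single spanning delins.
* The trend test's normal approximation is poor below ~5 sites per
  populated bin; the permutation cross-check in the tests covers the
  regime the pipeline actually runs in.
* Scanner throughput is adequate for gene-scale and chromosome-arm inputs,
  not optimised for whole-genome scans.
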