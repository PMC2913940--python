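# Methods

This note records the statistical model behind `cndiff`, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical choices a maintainer would want to know.

## Segmentation (CBS)

Each chromosome's ordered, non-missing log2 ratios are treated as a circle.
For every arc `[i, j)` whose arc and complement both contain at least
`min_width` probes, the statistic is the two-sample mean difference scaled
by the pooled variance of arc and complement (pooled over n − 2 degrees of
freedom).  When both pieces are constant but unequal the statistic is
infinite; when the whole vector is constant it is 0.  The maximizing arc is
found exactly via prefix sums; ties in |T| — which arise systematically
between an arc and its complement — are resolved toward the
lexicographically smallest `(i, j)` using a relative tolerance of 1e-10.

Significance of a split is assessed by permutation: `p = (1 + #{shuffles
with max |T| ≥ |T_obs|}) / (n_perm + 1)`.  If `p < alpha` the vector is cut
at the arc boundaries (up to three pieces, since a maximal arc never spans
the whole circle) and the pieces are segmented recursively; otherwise the
piece is emitted as one segment.

Defaults: `alpha = 0.01`, `n_perm = 1000`, `min_width = 2`, matching the
method's original conventions; all are configurable.  No post-hoc pruning
or "undo" of adjacent segments is performed — the recursion's output is the
final segmentation.  Missing probes are excluded rather than imputed, so a
segment's probe count refers to observed probes only.  The bundled
simulation studies use `n_perm = 200`, which still resolves `p < 0.01`
(minimum attainable p = 1/201) at a fifth of the cost.

## Gain/loss calling

Within a sample, segment means are summarized by their unweighted mean μ
and sample SD σ (n − 1 denominator); a segment is called *gain* iff its
mean strictly exceeds μ + 2σ and *loss* iff strictly below μ − 2σ.  Two
consequences are worth knowing:

- With fewer than 3 segments the spread estimate is degenerate; such
  samples are called all-normal with a warning.  The rule needs a genome
  with enough chromosomes/segments (≈10+) to behave well — on toy two-
  chromosome inputs a large real alteration can inflate σ enough to mask
  itself.
- Because σ is estimated per sample from few segment means, occasional
  whole-chromosome noise segments are called gain/loss.  These spurious
  calls are cohort-symmetric and are absorbed by the downstream exact test
  (verified by the null-calibration experiment).

Calls are projected onto a fixed-width grid (5 Mb default, restarting at
each chromosome, last region truncated).  A region takes the state class
covering the largest bp extent; normal loses ties to non-normal, and a
gain/loss tie goes to the segment deviating more from μ.  Regions with no
overlapping segment are `no_data` and drop out of that region's test.

## Cross-cohort exact test

Per region, the 3×2 table (gain/normal/loss × cohort) is tested exactly:
conditioning on the margins, table probabilities are multivariate
hypergeometric, and the two-sided p sums the probabilities of all tables no
more probable than the observed one (relative tie tolerance 1e-7).
Enumeration is over the two free cells of one column, with log-gamma
arithmetic and normalization by the total enumerated mass.  P-values are
left unadjusted in the screening workflows by design — the screens are
exploratory and their thresholds (p < 0.05 strict; p ≤ 1e-4 inclusive
after a ≥10 % alteration filter) are stated contracts, not error
guarantees.

The alteration-frequency filter of the dense-platform workflow is computed
over the pooled samples by default; `min_frac_scope` switches to per-group
("each") or at-least-one-group ("either") readings, since "altered in at
least 10 % of the samples of both cohorts" is genuinely ambiguous.

The qualitative direction class is defined operationally (no standard
definition exists): one cohort "wins" outright when its alteration
frequency is ≥ 2× the other's; otherwise, if both frequencies reach 0.15
and the cohorts' dominant non-normal states differ, the region is
"altered in both, different directions"; otherwise the higher frequency
wins.  The 2× ratio and 0.15 floor are exposed as parameters.

## Concordance and clustering

Gene-level tests compare expression between carriers of a gain (or loss)
and copy-neutral samples, separately per cohort, using the classic
pooled-variance two-sample t-test (a Welch flag exists).  Genes map to the
grid region containing their midpoint, avoiding double counting at bin
edges.  Contrasts with fewer than two samples in either arm are skipped,
not errored.  Adjustment is Benjamini–Hochberg by default (Bonferroni and
Holm available) across all tests performed in the call, with significance
declared at adjusted p < 0.05.

Sample clustering uses average linkage on 1 − Pearson correlation across
genes; the tree is cut into two clusters and the misclassification count is
the number of samples on the wrong side under the better of the two
cluster-to-cohort assignments.  Zero-variance samples have undefined
correlation and are dropped with a warning.

## Cytoband catalogs, overlap, enrichment

Catalog labels follow cytogenetic nomenclature: a bare band (`3q26`)
resolves to the union of the band and its sub-bands; a range
(`5p15-p14`, `20p11-20q11`) resolves from the first matched band through
the last in genomic order, crossing the centromere when the arms differ.
Two catalog entries overlap when their resolved intervals share ≥ 1 bp.
Because a broad entry can graze a focal entry that another broad entry
already matched, raw overlapping *pairs* can outnumber distinct overlap
*loci*; `overlap_loci` merges pairs sharing an interval or a member, and
the bundled 27-entry × 23-entry platform catalogs give 5 pairs collapsing
to 4 loci.

The bundled ideogram is **synthetic**: band names and ordering follow
standard human nomenclature, but coordinates are generated stand-ins
(contiguous, non-overlapping per chromosome).  Catalog intersection depends
only on band identity and ordering, not on physical coordinates, so the
overlap structure is faithful; absolute bp spans are not.

The EASE score for a query of size n overlapping a K-gene term in k genes
within an N-gene background is `P(X ≥ k − 1)` for hypergeometric X — the
one-sided Fisher tail after discounting one overlapping gene.  It is 1 for
k ≤ 1 and always ≥ the unmodified one-sided p.  Both the screening
threshold (EASE ≤ 0.1) and the significance level (EASE < 0.05) are
reported separately, as their interplay is convention-dependent.

## Synthetic-data generator

`simulate_cohort` draws, per sample, probe noise `Normal(baseline, σ)` on a
regular probe lattice (1 Mb BAC-like or 9 kb oligo-like spacing) and adds
±δ over each planted region the sample carries; carriage is an independent
Bernoulli draw with the sample's cohort frequency.  Defaults are the
study-design conditions the pipeline targets: 20 vs 21 samples, σ = 0.1
log2 units, δ = 0.6, baseline 0.  A `bac_duplicates` flag averages two
independent spot draws per probe (σ effectively /√2), mimicking
duplicate-spotted clone arrays.  Randomness derives from one seed expanded
into counter-based per-sample substreams, so output is independent of
evaluation order.

`simulate_expression` places genes evenly inside planted regions and draws
`baseline + β·s + Normal(0, sd)` with s = +1/−1/0 for gain/loss/neutral
carriage.  `simulate_clinical_table` samples age, stage, and Gleason strata
with the frequency-matched cohort proportions and PSA from truncated
normals (ranges [4, 17] and [3, 17] ng/mL); the location parameter is
solved numerically so the *truncated* mean matches the design means 8.5
and 8.3, which leaves the realized SD slightly below the nominal 3.5/4.0.

What the generator does **not** emulate: tumor-purity dilution of the
log2 signal, GC/wave artifacts, probe-specific response, partial-region
carriage (carrier state is whole-region by default), sex-chromosome
reference offsets (autosomes only), and correlated noise.  Passing the
bundled experiments therefore demonstrates the statistics behave correctly
under the stated noise model, not that the pipeline is robust to every
artifact of real arrays.

## Reference experiments and problem sizes

The `experiments` module fixes the desk-scale study conditions used by the
tests and the acceptance script:

- **Null calibration** — 8 synthetic chromosomes × 125 Mb (200 five-Mb
  regions), 2 Mb probe spacing, 40 planted CNVs carried at 30 % in *both*
  cohorts; one replicate of 20 vs 21 samples.  The per-region rejection
  rate at 0.05 must stay within 3 Monte-Carlo SEs of the nominal level; in
  practice the exact conditional test is conservative and the observed rate
  is near 0.
- **Planted-region recovery** — default genome (8 × 40 Mb, 1 Mb spacing),
  one 5 Mb gain with δ = 0.6, σ = 0.1, frequencies 0.5 vs 0.05; the region
  must survive the p < 0.05 screen in ≥ 90 % of 100 replicates.  Note the
  experiment has a hard statistical ceiling below 100 %: even with perfect
  carrier detection the region only survives when the exact test on the
  drawn carrier counts (Bin(20, 0.5) vs Bin(21, 0.05)) rejects.
  `experiments.recovery_ceiling` simulates that bound (the acceptance
  script reports it next to the achieved rate), so observed recovery a few
  points below the ceiling reflects carrier-draw randomness plus a small
  detection loss from the ±2σ calling rule, not a segmentation failure.
- **Concordance power** — truth-derived region calls (isolating the
  expression statistics from segmentation noise), 10 genes per region,
  noise 0.5: β = 3 must make ≥ 90 % of in-region tests significant after
  adjustment; β = 0 must keep the significant fraction ≤ 0.05.
- **Clustering separability** — 19 vs 14 samples with opposite-carrier
  expression blocks (β = 5): zero misclassified samples.

## Known limitations

- The permutation p-value is exchangeability-based; heavy autocorrelation
  in real probe noise would make splits anti-conservative.
- The ±2σ calling rule adapts to each sample's segment-mean spread, so a
  genome dominated by true alterations raises its own thresholds; this is
  inherent to the rule, not an implementation artifact.
- The grid count over a genome is `Σ_c ceil(L_c / width)` and therefore
  depends entirely on the supplied chromosome-length table; no particular
  total is asserted.
- Exact-test cost grows with the first column's sum squared; cohorts of a
  few hundred samples are fine, biobank scales are not the target.
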