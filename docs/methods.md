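# Methods

This note documents the models implemented in `lineageseq`, the choices
made where the design was genuinely open, and what the simulator does and
does not emulate.  It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Setting

A founding cell grows through an observed (or inferable) binary division
tree; a subset of terminal cells is expanded into subclonal populations
and whole-genome sequenced at moderate depth (~35×).  Somatic SNVs that
arose on a lineage segment — one or more consecutive cell divisions
between resolved branch points — are clonal in every subclone below that
segment and absent elsewhere.  The package's job is to recover those
variants jointly across subclones, assign them to segments, and quantify
mutation rate and spectrum.

## Coincident grouping and the membership posterior

Raw per-subclone SNV calls (from any pairwise caller, de-duplicated on
locus + alt + subclone) are grouped by identical substitution at an
identical locus.  Variants observed in all subclones are set aside as
founder variants (present before the lineage started); variants in
exactly one subclone go to the leaf-variant stream; the rest are
*coincident candidates*.

Each subclone at a candidate locus is assigned to the variant or the
reference group, and the assignment is scored with the binomial
membership posterior `P1/(P1+P2)` where `P1`/`P2` are binomial pmfs of
the observed alt count under the assigned/non-assigned group's alt
probability.  All pmfs are evaluated in log space; the posterior is a
logistic of the log-likelihood difference, so scaling both likelihoods
cancels exactly.  Group quality = the minimum posterior over samples;
the default acceptance threshold is 0.99 with strict `<` rejection.

Open parameters, with defaults and rationale:

| parameter | default | meaning |
|---|---|---|
| `f_alt` | 0.5 | clonal alt fraction in the variant group (het, diploid); `m/CN` available for other ploidies |
| `eps_ref` | 0.005 | alt fraction expected from sequencing error in the reference group |
| `q_threshold` | 0.99 | minimum min-sample posterior |
| `min_alt_reads` | 5 | minimum alt reads per variant-group sample |

The two group probabilities are not uniquely pinned down by the method's
description (an alternative is to centre them on per-locus empirical
allele-fraction means, which the three-group same-site scorer does); the
fixed-canonical-probability default reflects the observed clonal
allele-fraction peaks at 0.5 and 1.0 set by local ploidy.  Samples with
zero coverage contribute a neutral posterior of 0.5 rather than failing
the group: absence of reads is evidence for neither group.

The LOH filter flags variants whose pooled carrier alt fraction is
> 0.85 (with reference fraction < 0.85): such sites are more likely
allelic imbalance over a germline het than a de novo substitution.
Flagged variants are excluded from the call set but retained in a side
channel.  Note that this also removes genuinely hemizygous (copy-number
1) de novo variants; the haploid-territory rate validation therefore
works from the unfiltered variant stream.

## Calling with a lineage prior

*Method 1 (tree supplied).*  For each candidate locus the min-sample
posterior is evaluated for every tree-consistent clade (all subtree leaf
sets of size 2..n−1) plus every singleton; the candidate is assigned to
the argmax.  Ties break toward the smaller clade (conservative segment
assignment).  An argmax clade of size ≥ 2 above the threshold is a branch
variant on the edge above that clade's node; a singleton argmax is a leaf
variant; below-threshold candidates are reported as lineage-discordant
diagnostics, not imputed.

*Method 2 (tree inferred).*  Subclones are split per locus into
variant/reference groups by 2-group average-linkage clustering on alt
fraction; high-quality subclone sets are tallied into a clade-frequency
table.  Sets above a retention cutoff must form a laminar family (any two
disjoint or nested) — this is verified, with the conflicting pair named
on failure — and the family plus root and singletons is the inferred
tree.  The default cutoff is the largest gap in the sorted count
sequence, mirroring the evident high/low separation such tables show;
the cutoff is exposed (`min_count`) because gap placement is unstable
when true per-segment counts span a wide range.  Inferred trees carry
`n_i = 1` on every edge flagged as a *lower bound*
(`generations_exact=False`): shared variants carry no information about
how many divisions an edge represents, so rate estimation refuses such
trees unless explicitly overridden.

A pairwise dendrogram (distance = 1 − shared/total high-quality
coincident SNVs; average linkage by default, complete linkage available)
provides an independent visualization of the same structure.

First-division variants — whose clade is one of the two root subtrees —
cannot be oriented by an internal sister lineage; an outgroup sample's
counts or a reference allele list labels the ancestral allele, and the
fraction of homozygous→heterozygous orientations is reported as a
consistency check (a warning fires at ≤ 0.5).

## Performance estimation by scrambled labels

False positives: each candidate's subclone labels are reassigned by a
random scrambling pattern and the Method-1 scorer re-run; FP = scrambled
candidates that remain tree-consistent above threshold.  Patterns are
uniform random permutations rejection-sampled until every clade of the
consensus tree is disrupted (no true clade maps onto any tree-consistent
set), 10,000 by default, drawn per SNV.  False negatives:
`FN = max(0, #branch-predictions below threshold − scrambled ditto)`,
clamped at zero because the subtraction can go negative on small data.
Sensitivity = TP/(TP+FN) and specificity = TN/(TN+FP) are computed per
threshold over a grid to give a ROC-style curve; FP is asserted monotone
non-increasing in the threshold.

## Copy number and the effective genome size

Binned coverage (10-kb bins, median-normalized) from a pure subclonal
population is proportional to integer local copy number.  A scaling
factor `s ∈ [0.25, 4]` minimizing `Σ_bins |s·c_b − round(s·c_b)|` aligns
coverage with integers (coarse 1e-3 grid, 1e-5 refinement; the objective
is scale-periodic, so the smallest minimizer wins ties).  Scaled coverage
enters a 6-state HMM (states 0–5) with Cauchy emissions centred on the
state value — heavy tails absorb mappability outliers without breaking
segments.  One shared scale parameter γ is learned numerically in the M
step (bounded scalar optimization); transitions and the start
distribution update in closed form from forward–backward posteriors;
initialization is self-transition 0.999, γ = 0.1, reflecting long
constant segments at 10-kb resolution.  EM stops at a log-likelihood
improvement < 1e-6 or 500 iterations and raises if the likelihood ever
decreases (bug guard).  The Viterbi path segments the genome;
`G = Σ_bins state × bin_length` is the copy-weighted effective genome
size used as the per-bp rate denominator.

## Mutation rate

Per-edge branch counts `y_i` over `n_i` divisions are independent
Poisson(λ·n_i).  With the improper gamma(0,0) prior,
`λ | y ~ Gamma(Σy, Σn)`; the point estimate is the posterior mean and the
95% interval is equal-tailed from gamma quantiles (a 10⁶-draw sampling
path is provided and agrees to sampling error).  Per-bp rates divide by
`G`.  The posterior is improper when Σy = 0; the estimator raises rather
than guessing a prior.

Haploid validation: variants in copy-state-1 segments with carrier alt
fraction > 0.9 and non-carrier reference fraction > 0.9 are counted over
the haploid territory; the CI comes from Poisson simulation at the point
count (10⁶ draws, 2.5/97.5 percentiles).

Dispersion diagnostics: per segment, the upper-tail probability of the
observed count under Poisson(λ̂·n_i) — exact by default; the
10⁶-simulation mode is available and agrees to Monte-Carlo precision.
Expected p-values come from replicate count sets simulated under the
fitted model; both sides are sorted and log10-transformed into a QQ
table.  One-tailed (upper) p-values are the default with a two-tailed
option; uniform-rate data sit on the diagonal, gamma-mixed
(overdispersed) segment rates bend the tails off it.

## Spectra and genomic context

Substitutions are expressed on the pyrimidine strand and binned into 96
channels — six substitution classes × four 5′ × four 3′ bases, ordered
alphabetically within each class block (`A[C>A]A` … `T[T>G]T`).  Variants
without a full ±1 bp context (contig edge, N) are skipped and counted.
Cosine similarity between spectra carries a 95% CI from 10⁴ multinomial
bootstrap resamples of each variant list.

Region enrichment (genic/exonic or timing classes) compares observed
variant counts per class with expectations proportional to copy-weighted
class territory; expected counts are normalized over the supplied
classes so they sum to the classified total exactly.  Significance is a
one-tailed binomial test with the direction chosen by the observed sign
(the convention is not otherwise pinned down), P < 0.01; CIs are
bootstrap quantiles.  Replication timing classes: early ≥ 60,
late ≤ 33, intermediate between; replication direction from the timing
slope, right-replicating for 0.1 < slope < 0.3 units/interval and
left-replicating for the mirror window, with finite-difference slopes
computed from a value track when no slope column is supplied.

Replication-class asymmetry: the 12 reference-strand substitution rates
(per Mb of matching base territory) are folded into 6 leading-strand
pairs — a pyrimidine substitution in left-replicating territory pools
with its purine complement in right-replicating territory.  Rate CIs are
Beta(n+1, N−n+1) quantiles; the asymmetry is log2 of the complementary
count ratio with a CI from 1000 sampled beta pairs and a binomial
p-value under the base-composition null.

Frozen-signature projection: given a 96×K signature matrix W (columns
normalized), activities H are fitted by multiplicative KL updates with W
strictly frozen, uniform positive deterministic initialization,
convergence at relative KL change < 1e-8 or 10⁴ iterations, and a
per-update assertion that the KL objective never increases.  Subtracting
signature k removes `H[k, j]` (W columns sum to 1) from segment j's
count, floored at zero, before rates are recomputed.

## Correlated events

*Clusters/MNVs.*  Per-variant nearest-neighbour distances are computed
within each sublineage and, separately, to the nearest variant of a
different sublineage; the null is uniform placement of the same number
of variants (10³ simulations).  Distance ≤ 1 bp defaults to
"multinucleotide", ≤ 100 bp to "clustered"; the cutoffs are explicit
parameters because only "closely linked" is prescribed.

*Same-site events.*  Loci with two distinct alternate alleles are
3-way clustered (reference/alt1/alt2) on the two alt fractions; cluster
centres parameterize multinomial likelihoods over (ref, alt1, alt2)
counts and the event quality is the minimum sample posterior
`P1/(P1+P2+P3)`.  An event is accepted when quality ≥ 0.99, both alt
sets are tree-consistent and disjoint, and both pass the read-support
filter.  The two count-table rows at such a locus share the reference
count column; total coverage is ref + alt1 + alt2.

*Overlap and congruence.*  The chance of k same-position coincidences
among n variants is tested against a per-variant Bernoulli rate
estimated from an independent comparison set (binomial simulation, 10⁵
draws, add-one smoothing; the exact binomial tail is the oracle).  Two
segments are *congruent* when the MRCA of their clades is not the root —
both fall inside one proper sublineage, the transmission path a
persistent lesion implies.  The congruence null draws segment pairs from
the empirical call-set distribution (5×10⁵ replicate sets) and reports
the probability that all observed events would be congruent by chance.

## The simulator

`simulate_lineage` draws a complete binary division tree, samples
terminal cells, collapses unobserved divisions into multi-division edges,
and plants per-edge mutation counts from Poisson(λ·n_i) (or a
gamma-mixed alternative for overdispersion).  Mutations attach at
division granularity, not in continuous time, matching the per-division
rate model.  Reads: depth ~ Poisson(mean_depth · CN/2), carrier alt
reads ~ Binomial(depth, m/CN), non-carrier alt reads at the flat error
rate; same-site loci draw one multinomial per subclone so the two rows
share reference coverage.  Lesion events place two alts on two disjoint
segments under a common non-root ancestor; MNV clusters place a
companion substitution within a window on the same edge.  Independent
placements are collision-free by redrawing, so same-site events exist
only where planted.  Defaults mirror the measured regime of a
proofreading-deficient line: 173 SNVs/division, 35× depth, 0.5% error,
11 subclones from a 4-generation tree; the default genome is a single
50-Mb chromosome so that desk-scale runs stay fast — per-division rates
scale with genome length, so tests that compare against the planted rate
always do so in the simulator's own units.  An `emit_reads=False` mode
skips read emission for count-level Monte-Carlo studies.

Not emulated: indels and structural variants, base/mapping quality,
GC/mappability coverage bias, subclone cross-contamination, and
alignment artifacts.  A green simulation test therefore establishes the
statistical machinery, not robustness to upstream artifacts.

## Numerical notes

- All posteriors via log-pmf differences (no underflow to total ≥ 60 and
  far beyond); equality with direct pmf evaluation to 1e-12 is asserted
  in tests.
- Viterbi and forward–backward run in log space; Viterbi is verified
  against exhaustive path enumeration on tiny chains.
- Deterministic ordering everywhere outputs are serialized: loci by
  (chrom, pos, ref, alt), subclone sets lexicographically.
- All randomness flows through `numpy.random.default_rng(seed)`;
  identical config + seed gives byte-identical outputs.

## Known limitations

- The two-group scorer assumes a single clonal allele fraction per
  group; heavily subclonal leaf variants score poorly by design.
- Method-2 trees have no division counts; rates from them are refused
  without an explicit override.
- The LOH filter removes true hemizygous variants (see above).
- The scramble null estimates specificity against label permutations
  only; it cannot see systematic artifacts shared across subclones.
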