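# Methods

This note documents the model, the numerical choices, and the synthetic
data underlying shatterscan, in the order the pipeline applies them.

## Breakpoints and densities

Every translocation contributes four breakpoints (both ends of the
fragment on the source chromosome, both ends on the destination);
every CNV contributes two. A variant touching a chromosome terminus
places its breakpoint just outside the sequence (position 0 before the
first base, length + 1 after the last), so terminal events are not
silently truncated. LOH segments and insertions do not enter the
density scan; they only inform the heterozygosity and insertion
hallmarks.

Per-chromosome SV density is breakpoints per bp. The mean and standard
deviation of the densities are taken across *all* chromosomes of the
genome model, including those with zero breakpoints. All standard
deviations in the package are population (n-denominator) standard
deviations: on the tiny count vectors involved, the sample estimator
would inject an arbitrary inflation and, in the degenerate one-element
case, be undefined.

## Sliding-window scan

The genome is divided into contiguous bins of `bin_size` bp (default
1000). A window spans `window_size` bins (default 10000, i.e. 10 Mbp)
and advances one bin at a time; the final windows shrink to the
chromosome end, and a chromosome shorter than one window becomes a
single whole-chromosome window. The defaults (bin 1000, window 10000,
hence a 10 Mbp window advancing in 1 kbp steps) trade resolution
against memory; a coarser step is available by raising `bin_size`.

Window counts are z-scaled against the mean and population sd of all
windows genome-wide — "highly mutated" is defined relative to the whole
genome, not per chromosome. Windows with z ≥ `window_z_threshold`
(default 2.0, a conventional two-sigma enrichment; the threshold itself
is not prescribed by the method definition) are merged when they
overlap or abut, producing disjoint, sorted regions. When every window
has the same count (sd = 0) the genome is uniform and no region is
emitted. An SV is attached to a region when any part of its interval
(either end, for a translocation) intersects the closed region
interval.

## Hallmark scores

**Genome localization.** For the region's chromosome,
`z = (density − mean)/sd`, converted to a right-tailed p-value `p`
under the standard normal; score `(0.5 − p)/0.5`. Chromosomes at or
below the mean score 0 without a test (avoiding multiple testing);
sd = 0 also scores 0.

**Chromosome localization.** Observed region breakpoint count `O`
against expectation `E = chromosome density × region length`, compared
with Pearson's chi-squared, 1 df. The statistic is computed on counts
(the unit-free form; raw density differences would carry units). The
mapping to [0, 1] is the lower-tail chi-squared probability, gated on
enrichment: `O ≤ E` scores 0, since localization means *elevated*
density. `E = 0` with `O > 0` scores 1.

**Copy-number aberrations.** CNV segments in the region are laid onto
a diploid baseline (`normal_copy_number = 2`, configurable). Every
boundary where the state changes is one oscillation; an isolated
aberrant segment contributes two, and a transition directly between two
aberrant states counts once in each state's tally. Overlapping
same-state segments are merged; where different states overlap, the
state further from normal claims the shared bases (logged). With
per-state oscillation counts `cₙ`, the states whose z-score exceeds
`significance_z_cutoff` (default −2, dropping the bottom few percent of
noisy states; all states pass when sd = 0) are significant, `N` of
them. The score is `(1/N)(1 − 1/(1 + log₂ x))` with
`x = Σ cₙ / (2N)` over significant states, clamped to [0, 1]; no
aberrant state, or `x ≤ 1` (no more oscillation than one isolated
segment per state), scores 0. The algebraic grouping admits more than
one reading; this parse preserves the intended ordering (one state
with 15 oscillations outscores three states with 5 each).

**Translocation localization.** Partner chromosomes are those sharing a
translocation with the region; the end overlapping the region
designates the other end's chromosome as the partner, and that other
end contributes its two delimiting breakpoints. Intrachromosomal
translocations count once per end on the shared chromosome. Partner
counts pass the same z > −2 significance filter, giving `N` significant
partners and their total count `c_T`. Per partner, the ordered
breakpoints yield adjacent separations; separations with z > 2
(`outlier_z_cutoff`) are dropped so several tight clusters separated by
long gaps still read as clustered, and the spread is the mean of the
remainder (with fewer than two breakpoints the spread defaults to the
expected spread — neutral). The expected spread is the uniform-placement
mean gap, `chromosome length / (breakpoints + 1)` — the natural null
for unclustered breakpoints. The spread factor is
`log(1 + spread) − log(expected)`; the weighted sum is
`Σ (cₙ²/c_T) · exp(−spread factor)` over significant partners — the
exponential form keeps the scale positive, amplifies spreads tighter
than uniform, and damps looser ones, and makes the log-base choice in
the spread factor immaterial. The score is `first × second`, where
`first` is 1 for `N = 1`, 0 for `N >` `max_significant_partners`
(default 8), otherwise `1 − 0.10(N − 2)` clamped at 0, and `second` is
`1 − 1/log₂(1 + weighted sum)` clamped to [0, 1].

**Retained heterozygosity.** The space between CNVs inside the region
is assumed heterozygous. The score is one minus the fraction of that
space covered by observed LOH; no predicted-heterozygous space scores
0, and absent LOH data scores 1 (nothing contradicts the prediction).

**Insertions.** The fraction of the region's translocation breakpoints
with a short insertion within `insertion_window` bp (default 10,
inclusive: exactly 10 bp away counts).

**TP53.** A user flag (e.g. from immunohistochemistry) sets the score
to 1 or 0. Separately, any SV or insertion overlapping the TP53
interval (default chr17:7,570,000–7,590,000, GRCh37; configurable for
other builds) is annotated in the report without altering any score.

**Combination.** The final score is the weighted sum of the seven
sub-scores. The default weights are consumed as constants (their
derivation by multi-criteria analysis is out of scope here); they are
printed to four decimals and literally sum to 1.0001, so the
configuration validator accepts sums within 0.001 of 1. Scores above
`call_threshold` (default 0.37) are flagged; nothing is filtered. Call
quality values are parsed and can gate input (`min_quality`) but do not
enter any score.

## Degenerate inputs and ties

sd = 0 cases: all values significant in the significance filter, score
0 in genome localization, no regions in the window scan. Empty
translocation or CNV *lists* are valid (a sample may genuinely have
none); passing no list at all is an error, as both inputs are
mandatory. Ties in the final-score ordering break by genome order then
region start, so reports are fully deterministic; floats are serialized
with six decimals and re-parse exactly.

## Synthetic data

The generator exists so the whole pipeline is testable without
controlled-access clinical data. One seeded RNG stream drives all
sampling; identical parameters give byte-identical files.

`simulate_chromothriptic` plants one event: by default 20 disjoint
single-deletion-state CNV segments oscillating with normal gaps across
a 30 Mbp region of chromosome 8 (GRCh37 lengths), 24 translocations
round-robin over 3 partner chromosomes with all breakpoints confined to
2 Mbp clusters, short insertions within 10 bp of half the event
breakpoints (`insertion_rate = 0.5`), and LOH placed only over the
deleted segments so heterozygosity between segments is retained
(`loh_gap_fraction` erodes it on demand). Event sizes sit at the scale
of documented chromothriptic chromosomes; call qualities are drawn from
[0.8, 1.0] so default quality filters pass everything.

A diffuse background is overlaid on positives and used alone as the
negative control. It emulates the residual calls SV pipelines leave on
unremarkable (normal) samples, whose defining property is *few SVs that
are not localized anywhere*: 12 CNVs with same-chromosome midpoints at
least 50 Mbp apart, states drawn from six distinct aberrant levels;
10 translocations whose chromosome pairs form a random perfect matching
(no chromosome recurs) and whose recorded fragments span 50–95% of
their chromosome, so partner breakpoints are at least as dispersed as
uniform placement predicts; 30 insertions and 12 LOH segments placed
uniformly (chromosome chosen proportional to length). Under this
design no background region can contain two CNV segments, attach two
translocations to one partner, or express the insertion hallmark except
by bp-scale coincidence — so background scores are bounded near the sum
of the genome-localization, chromosome-localization and heterozygosity
weights (0.349), below the 0.37 call threshold. The call counts were
chosen so a background sample yields roughly the dozen candidate
regions, none above threshold, that SV pipelines typically leave on
matched normals. Two caveats follow from the construction: background
region scores concentrate higher than ideal, because sparsely
triggered windows are intrinsically enriched (a window flagged at
z ≥ 2 sits near twice its expectation, so the chi-squared hallmark
saturates); and the structural guarantees
(non-recurrent partners, spaced CNVs) are stronger than real normal
data, where rare clustered artifacts do occur. Passing the
discrimination test therefore shows the pipeline separates planted
events from unclustered noise at realistic call counts — not that the
0.37 threshold is robust to every artifact a real caller can produce.

The generator does not simulate reads, sequence content, quality-score
structure, or caller-specific error models; it writes the same input
dialects the parsers read, which keeps the round trip honest but means
converter bugs for real callers' formats are out of its reach.

## Problem sizes

Tests and the acceptance checks run the full pipeline on the complete
24-chromosome GRCh37 genome model (≈3.1 Gbp, ≈2.9 million windows at
the default bin and window sizes); the discrimination check uses 100
planted-event and 100 background simulations. A single sample scores in
well under a second on one core, the window scan being a single
cumulative-sum pass per chromosome.

## Known limitations

- Scores depend on the upstream caller's sensitivity and format
  conversion; scores from different callers are not directly
  comparable.
- The chromosome-localization hallmark saturates for any sparse sample,
  as noted above; it separates poorly on its own and relies on the
  weighted combination.
- Hallmark weights are fixed constants; re-deriving them for a new
  cohort is out of scope.
- The TP53 interval default assumes GRCh37 coordinates.
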