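# Methods

This note records the models behind `sedapop`, the parameter defaults and why
they hold, the numerical conventions, and what the synthetic validation does
and does not demonstrate.

## The setting

A sediment sample yields millions of short degraded fragments from many taxa.
For a dominant taxon whose organellar genome reaches high fold coverage, the
pooled reads are a population sample: several haplotypes at unknown
proportions. Two artefacts dominate such data: post-mortem cytosine
deamination, read as C→T near the 5′ fragment end and G→A near the 3′ end,
and the short fragment length itself, which limits how much phase information
any one molecule can carry. Every design choice below is a response to one of
these two facts.

## Synthetic data generator

`make_haplotype_set` plants variant sites on a uniform-random reference.
Transversion sites are biallelic purine↔pyrimidine pairs; every planted site
is polymorphic *within the mixture* (haplotype assignments are never all
reference or all alternative). "Linked pairs" plant two transversion sites a
set gap apart at which all K ≤ 4 haplotypes carry distinct two-base
combinations — the ground truth for the phasing estimator.

`simulate_reads` draws, per read: a source haplotype with its mixture
probability, a log-normal fragment length rejection-truncated to
[35, 160] bp (the bounds real filtering imposes; no specific length law is
canonical for sediments, so the log-normal is a modelling choice with
`mean_length` and `spread` exposed), and a uniform start. Half the fragments
are sequenced from the reverse strand. Damage is applied in **read**
coordinates — after reverse-complementing minus-strand fragments, matching
the biological mechanism — with position-z probability `d·decay^z` from the
relevant end (defaults d5 = d3 = 0.3, decay = 0.5, the terminal rates typical
of well-preserved late-Pleistocene material), then a uniform sequencing error
(default 0.002) that hits each alternative base with probability 1/3. Base
qualities are constant at the Phred equivalent of the error rate. Two samples
of differing preservation are emulated by `mean_length` (65 vs 55 bp
defaults).

Not emulated: GC bias, PCR duplicates beyond exact copies, indels (the
variant model skips them), paired ends (merged single reads only),
within-read quality variation, and contamination by other taxa. Passing
tests therefore validate estimator logic under the stated noise model, not
robustness to every artefact of a real library.

## Read filtering

Reads shorter than 35 bp are removed, then reads whose DUST low-complexity
score exceeds 1. The DUST variant is pinned exactly: over every 64 bp
sliding window, count each overlapping 3-mer (triplets containing N are
skipped) and score `Σ c(c−1)/2 ÷ (w−1)` over the w counted triplets; the
read's score is the maximum over windows. A 35 bp homopolymer scores 16.5; a
read of all-distinct 3-mers scores 0. A read scoring exactly the threshold
is kept. Reads more than half N are removed as degenerate.

## Mapping, duplicates, pileup

The internal mapper is deliberately minimal and ungapped: exact 16-mer
seeding at every read offset, candidates scored by Hamming distance on both
strands, ties resolved to the lowest reference start then the plus strand;
reads above `max_mismatch_rate` (default 0.1, config-exposed) stay unmapped.
Because the simulator emits no indels and the variant model skips them,
gapped alignment would add cost without exercising anything; real-data users
ingest an external SAM (ungapped records only) through `sedapop.io.read_sam`
and get byte-identical pileups for identical placements.

Two duplicate notions exist, as in library-preparation practice:
*exact-sequence* duplicates (identical read-orientation sequence string,
wherever mapped) are collapsed by keeping one copy uniformly at random —
this choice is replicated in the proportion estimator to expose its sampling
effect — and *coordinate* duplicates (same start, strand, and length) are
collapsed deterministically to the highest mean-quality copy, first-in-input
on ties. Coordinates are 0-based half-open everywhere internally; emitted
tables use 1-based positions where the format convention demands it.

## Damage model

The profile reports, for each distance z from the read end (25 positions by
default, capped at 160), the fraction of reference-C positions read as T
(5′) and reference-G positions read as A (3′), after strand normalisation.

The per-read post-mortem-damage score is a log-likelihood ratio (natural
log) between an ancient model, in which a reference C at 5′ distance z is
read as T with probability `D(z) = d·decay^z`, and a modern model where only
the quality-implied error ε (floored at 1e−4) applies: an observed
deamination-type mismatch contributes `log(D/ε)`, a matching C (or G)
contributes `log((1−D)/(1−ε))`, and all other positions contribute 0. A
single terminal C→T at Q30 with d = 0.3 scores log(300) ≈ 5.7, so genuinely
damaged reads clear the ≥3 retention threshold on one observation;
damage-free reads can never score above 0. CpG-specific behaviour is not
modelled. Prior parameters default to the generator's damage defaults and
are exposed.

## Composite consensus

Majority rule per covered position; ties prefer the current seed base
(reference-stable) and otherwise the alphabetically first leader. Uncovered
positions take the seed base (`reference_fill`, used inside the iteration)
or N (`no_fill`, for reconstructions from distant seed genomes where filling
would fabricate sequence). "No longer improvable" is pinned as two
successive consensus sequences being identical, with a safety cap of 10
iterations; a non-converged or unmappable run is returned flagged, not
raised. Gaps (depth 0) and low-coverage runs (0 < depth < threshold) are
reported as intervals; they are never auto-filled, but `splice_patches`
accepts externally assembled patch sequences with exact 20 bp flanking
anchors, keeping de-novo assembly outside the package boundary.

## Variant sites and haplogroups

An allele requires at least two supporting reads. A site is considered
where at least two alleles meet that floor, its quality is the Phred-scaled
exact binomial upper tail of the second-largest allele count against the
column's depth-weighted quality-implied error rate, and it must pass
quality ≥ 30 and depth ≥ half the mean depth (mean over *all* positions,
zeros included, halved and floored — the averaging convention is pinned
here).

The analysis restriction then applies, in this order: alleles below the
rare-allele floor (0.1, strict `<`; exactly 0.1 survives) are removed and
the remaining proportions renormalised — site proportions are proportions
*of the reference and alternative alleles*, so noise alleles leave the
denominator — and only sites whose surviving allele pairs are all
transversions are kept. The order matters: terminal deamination of a G
allele at a genuine C/G transversion site plants a minor A allele, and
testing transversion purity before removing rare alleles would silently
discard exactly the sites the restriction is meant to protect.

High-frequency variants are the alleles present in the composite genome —
membership by presence, not frequency; a site whose composite base is not
among its alleles is flagged and contributes to the low set only. The
high/low allele choices render into the two haplogroup consensus sequences.

Allele proportions are estimated from reads mapped separately against both
haplogroup sequences and merged (the same read appears twice and collapses
in exact-sequence de-duplication), so neither haplogroup enjoys a mapping
advantage. Five replicates re-draw the random de-duplication from labelled
substreams; each replicate reports per-site and genome-wide mean
alternative proportions relative to the composite base.

Damage-restricted validation re-calls variants using only reads with PMD
score ≥ 3, at relaxed thresholds (quality ≥ 3, depth ≥ 3), and reports the
fraction of the original transversion sites recovered by position.

## Minimum haplotype count

Transversion sites pooled across samples are chained greedily left to right
into windows: a site joins the open window while the total span stays
≤ 35 bp; windows need ≥ 2 sites; each site belongs to one window.
Alternative chainings are not enumerated — the greedy rule *is* the
definition, and the tests hold it to an independent oracle of the same rule.
Per sample, a read contributes to a window only if it covers every site;
its allele combination is the concatenated bases (N-containing combinations
are excluded). Combinations with fewer than 3 reads or under 15% of
spanning reads (both strict `<`; the boundaries survive) are removed as
noise; the window's count is the number surviving. The per-sample summary
averages counts over windows with spanning reads; the overall minimum
estimate is the **maximum** count over windows and samples — a window
exhibiting k phased combinations is direct evidence of at least k
haplotypes, and no window can ever exhibit more combinations than exist, so
the estimate is a lower bound on the truth (verified across seeds in the
property suite). Replicate de-duplicated read sets are each scored and the
per-replicate spread reported.

## LCA and summaries

Hits (12-column tabular format plus a taxon-id column) pass bitscore ≥ 35,
e-value ≤ 1e−5, identity ≥ 95%, query cover ≥ 95%; of the survivors, those
within 10% of the best bitscore (inclusive: ≥ 0.9 × best) vote, and the
query is assigned their lowest common ancestor. Taxa holding under 0.01% of
assigned queries are folded into their parents bottom-up, deepest node
first, so weak sibling taxa can pool support at a shared ancestor before
that ancestor is itself judged; support is evaluated against the merged
per-sample query set. The competitive filter retains a read whose
reference-panel bitscore beats its best database hit, or whose best-hit LCA
falls within the target genus. Summary tables report N, I = 100·N/identified
and A = 100·N/analysed, rounded half away from zero to two decimals (the
printed-table convention); the A denominator is passed explicitly, never
inferred.

## Determinism and problem sizes

One master seed; every stochastic stage derives an independent
`SeedSequence` substream labelled by stage and replicate index, so a single
replicate can be reproduced in isolation and identical seed + inputs give
byte-identical outputs (tested). The implementation is single-threaded;
`--threads` is accepted for interface compatibility and cannot affect
results.

The validation suite runs at desk scale by design: references of 1–10 kb at
30–100× coverage (a 10 kb end-to-end run takes well under a minute), with
the deamination-profile checks using ~45,000 reads for tight binomial
tolerances and the haplotype-recovery rate measured over 100 seeded runs at
1.1 kb/100×. These sizes give the stated statistical tolerances
(±0.03 on terminal deamination frequencies, ±0.05 on mixture proportions)
comfortable margins while keeping the whole suite in a few minutes.

## Known limitations

- Ungapped internal mapper: structural variation or indel-rich regions
  require externally produced alignments.
- The binomial site-quality model ignores correlated errors and mapping
  error; it is calibrated for the simulator's noise, conservative levers
  being the transversion restriction and the rare-allele floor.
- The minimum-haplotype estimate is exactly that — a minimum. Short
  fragments bound how many sites one read can span; haplotypes identical
  within every window are invisible, and low-proportion haplotypes
  (< 15% of spanning reads) are filtered as noise by construction.
- Windows are scored independently; no attempt is made to link windows into
  genome-scale haplotypes, which would require a reference panel.
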