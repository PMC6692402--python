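# Methods

This note documents the models and procedures chialoop implements, the
defaults and why they were chosen, what the synthetic-data generator
does and does not emulate, and the numerical conventions.

## Coordinates and formats

All internal coordinates are 0-based half-open (BED native); GFF3 input
is converted on read and output is converted back on write. "Overlap"
always means at least one shared base pair, so touching half-open
intervals do not overlap. Loops are stored with anchors in canonical
genome order for intrachromosomal pairs; the BEDPE dialect reserves
columns 7–9 for loop id, PET count and FDR and passes further columns
through untouched.

## Anchor/basal classification and gene models

A peak is an *anchor* iff it overlaps any loop anchor of its own mark;
cross-mark overlaps are deliberate, separate queries, never part of
classification. Genes are assigned by promoter overlap: the promoter is
[TSS − w, TSS + w) clipped to the chromosome, with w = 2000 bp by
default. The value is a convention, not an estimate — promoters are not
formally annotated in most plant genomes — and it is exposed as a
parameter and echoed in outputs. When a promoter overlaps both anchor
and basal peaks the anchor takes precedence (the gene demonstrably
participates in an interaction). Enlarging w can therefore only promote
a gene along unmarked → BP → PPI, a monotonicity the tests assert.

## Interaction domains (CIDs)

Two loops are connected when any anchor of one overlaps any anchor of
the other; components are the transitive closure, computed by a sweep
over sorted anchors with union-find (provably identical to the closure,
and tested against a cubic oracle). Loop *coverage* at a base pair is
the number of loops whose full span [anchor_a.start, anchor_b.end)
contains it; anchor-only coverage was rejected because chained loops
with disjoint anchors would never yield the continuous covered runs
that define a domain. Within each component's span, maximal runs with
coverage ≥ 2 (default) whose length lies in [min_span, max_span] become
domains. Defaults: min_span 10 kb; max_span 1 Mb for H3K9me2 and
RNAPII, 200 kb for H3K4me3. The coverage threshold quantifies
"low-coverage" trimming; 2 is the smallest value that distinguishes a
stack of interlocking loops from a single spurious long-range cluster.
Related segments merge domains separated by gaps ≤ 20 kb (default);
`min_pet_count` (default 1) optionally pre-filters weakly supported
loops.

The genome partition is exact integer set algebra per chromosome
(MID = K9 ∩ K4, HID = K9 − K4, AID = K4 − K9, TID = PII − (K9 ∪ K4),
GAP = complement); the module intervals provably tile each chromosome,
and the per-label base-pair totals sum to the genome size exactly.

## Contact maps and compartments

Contacts are positioned at anchor midpoints — deterministic and
span-preserving; tag-level positions are not available downstream — and
a contact enters the matrix only if its midpoint distance exceeds
8 kb, the inter-ligation threshold that separates genuine long-range
evidence from self-ligation noise. Binned matrices are balanced by
iterative correction: bins in the lowest 2% of marginal mass (and all
empty bins) are masked, then row/column biases are updated until
unmasked row sums agree within tolerance (non-convergence raises,
carrying the iteration trace). Compartments: per chromosome the
balanced map is distance-normalised (observed/expected with
distance-stratified means; empty distances imputed from the nearest
populated distance), the bin–bin Pearson correlation matrix is
column-centred, and its first principal component is extracted by power
iteration (tol 1e−8, max 10 000 iterations, positive-first-entry
tie-break before orientation). The sign is oriented so bins richer in
active-mark peaks are positive (A). The call is invariant to global
matrix scaling; chromosomes with fewer than 10 usable bins return NA
with a warning.

## Promoter–promoter networks

An anchor covering k promoters fans out to all k genes; multiple loops
between the same gene pair collapse into one edge carrying the loop ids
and summed PET count; self-pairs are counted, not edged. Degree counts
distinct gene partners. Subnetworks are connected components after edge
filtering (intra ≥ 4 PETs, inter ≥ 6 summed), ranked by node count with
deterministic ties (edge count, then smallest gene id), making the
output invariant to input edge order.

## Co-expression against distance-matched nulls

The statistic is the mean Pearson correlation over looped gene pairs,
computed pairwise-complete across tissues; pairs with fewer than three
shared tissues or a constant profile are dropped with a recorded
reason. Null A draws, for each observed pair at TSS distance d, a
same-chromosome gene pair with distance in [d(1−t), d(1+t)] (t = 0.1
default), uniformly *with replacement* from the pool of all eligible
pairs with the observed pairs excluded; null B restricts the pool to a
supplied marked-gene set. If no eligible pair exists the tolerance
doubles up to four times, then the pair is skipped (skips counted).
Interchromosomal pairs have no defined distance and are excluded with a
count. The test is one-sided by default (the claim is enrichment), and
the empirical p uses the plus-one correction, so it is never zero. For
null scoring with missing cells the standardised profiles treat NaN as
zero contribution, an approximation that is exact on complete data
(the generator produces complete matrices).

## Differential peaks

Peak sets from two varieties in one coordinate frame are merged by
≥ 1 bp overlap chains. Counts are normalised by median-of-ratios size
factors (optionally supplied). The test is deliberately simple rather
than a re-implementation of a full shrinkage estimator: a common
negative-binomial dispersion is estimated by method of moments from the
equal-mean identity E[(k₁−k₂)²] = 2μ + 2αμ², and each interval gets a
Wald z-test on the log ratio of normalised means
(variance 1/m₁ + 1/m₂ + 2α); at dispersion zero the exact conditional
binomial replaces it. Benjamini–Hochberg adjustment and the thresholds
adjusted p < 0.05, |log₂FC| > 1 define up/down/stable; log₂FC uses
pseudocount 1. Simulation at dispersion 0.1 (500 true-stable
intervals, 5 seeds) keeps the realised false-positive fraction of the
full up/down call well under 5%, which the thresholds make conservative
by construction. Variant attribution assigns a primary class by largest
overlapped bp with the fixed tie order PAV > InDel > SNP > inversion >
translocation. Variety-specific loops match anchors within a 2 kb slop
(symmetric by construction); causes follow the precedence
PAV-associated > mark-conversion > unexplained.

## eQTL loop support

cis means same chromosome and interval gap ≤ 1 Mb (containment ⇒ gap
0); everything cross-chromosome is trans. Support requires one loop
anchor on the eQTL interval and the other on the target promoter, in
either orientation, loops of any mark; contact frequency is the summed
PET count of supporting loops. The null simulates, for each real pair,
a random gene with a locus placed at a distance within ±10% of the real
distance (random chromosome pair for trans), scored identically, and
real vs simulated frequencies are compared one-sided by rank-sum. The
test demands at least 10 real pairs.

## Synthetic-data generator

The generator plants everything the pipeline is supposed to find, at
defaults chosen to be the validation conditions: a 2 × 5 Mb genome,
1000 genes, 20 tissues, 5 domains per mark (spans 150–400 kb for
H3K9me2, 50–150 kb for H3K4me3, 80–250 kb for RNAPII), an anchor
fraction of 0.43, a co-expression latent-factor loading ρ = 0.5, 500
eQTL pairs with a 12% planted support rate and a 24% trans share, and
geometric PET counts (heavy-tailed like real cluster files). Loops
inside a planted domain chain anchor i to anchor i+2 plus one
domain-spanning loop, so base-pair coverage is ≥ 2 across the entire
span and the planted boundary is exactly the coverage-threshold
boundary. Scattered isolated loops and the planted eQTL-connecting
loops are placed so their spans never stack ≥ 2 deep outside domains;
unsupported eQTL intervals are placed clear of every loop anchor, so
the planted support set is exact. Expression: members of a looped
component share a latent tissue profile, log-signal = √ρ·L + √(1−ρ)·ε,
exponentiated and rescaled to median FPKM 5 (strictly positive,
right-skewed). On the FPKM scale the pairwise correlation of a looped
pair is below ρ (the exponential transform attenuates it); tests
therefore validate against resimulation envelopes rather than ρ itself.
Determinism: each stage draws from a child generator keyed by
(seed, stage name), so adding a stage never perturbs another stage's
stream, and identical configs are byte-identical across runs.

What the generator does **not** emulate: real anchor-width and loop-span
distributions, transposable-element landscapes, centromeric enrichment
of heterochromatic contacts, expression compositionality, mapping or
peak-calling noise, and cross-variety coordinate divergence. Passing
the planted-recovery tests shows the algorithms are correct under the
stated generative assumptions, not that the defaults are tuned for any
particular real dataset.

## Problem sizes and design choices

The validation suite runs the full pipeline on the toy genome (seeds
1–5), 100-replicate calibration of the co-expression null at 199
permutations, power runs at 1000 permutations × 200 pairs, and 500
random-instance oracle comparisons per kernel — sizes chosen so the
whole suite completes in about a minute while keeping every Monte-Carlo
bound meaningful. The acceptance script reuses the same default
conditions at a single seed.

Known limitations: the coverage threshold and the "related segment"
gap tolerance are conventions where the underlying definitions are
loose — both are recorded in outputs; the differential test is a
deliberate simplification of shrinkage-based NB estimators and is
conservative at small replicate numbers; cross-variety analyses assume
inputs already lifted to one coordinate frame; and compartment calls on
sparse ChIA-PET-derived maps are only as good as the masking of
low-coverage bins.
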