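# Methods

## Coordinates and sequence normalization

All intervals are 0-based half-open internally; GFF3's 1-based inclusive
coordinates are converted exactly once, at the I/O boundary, and restored
on export. Sequences are upper-cased and RNA `U` becomes `T` on ingest so
k-mer counting sees a single alphabet. When a genome arrives as several
scaffolds, the longest is analyzed (ties broken by lexicographically
smallest id, for determinism; real assemblies never tie).

## Tetranucleotide composition track

Windows are `width` = 10,000 bases with `overlap` = 1,000 bases between
consecutive windows, i.e. a step of 9,000; the trailing partial window is
dropped, so a genome of length L yields `floor((L − width)/step) + 1`
windows. "Overlap of 1 kb" is read literally as shared bases; the common
alternative idiom (sliding *by* 1 kb, i.e. 9 kb of overlap) is available
by setting `overlap=9000`, and nothing downstream depends on which is
chosen beyond track resolution. Circular chromosomes are windowed
linearly — no wrap-around window; the cost is at most `width − 1`
uncovered bases at the origin.

Each window contributes the counts of all 256 tetranucleotides over
{A,C,G,T} on the given strand; 4-mers containing any other symbol are
skipped (windows are never discarded for containing Ns). An optional
strand-symmetric mode pools each 4-mer with its reverse complement;
it is off by default since single-strand counting is the conventional
signature. The window × 256 count matrix is column-centered (no variance
scaling — all windows have identical length, so counts are proportional
to frequencies) and projected onto its leading principal axis
(scikit-learn PCA, full SVD). PCA sign is arbitrary, so the axis is
oriented to make the largest-magnitude loading positive; the downstream
two-sided threshold is sign-invariant anyway. A zero-variance matrix
(all windows identical) yields an all-zero track with explained-variance
fraction 0 and a warning rather than an error.

## Hit-organism frequency scores

Inputs are tabular protein homology results (the 12-column BLAST/DIAMOND
dialect) with a subject-organism label per hit (13th column or a
separate subject→organism map). For every query the first `top_k` = 5
hits are examined in the search tool's reported order (an option
re-sorts by bitscore); hits whose organism is on the excluded-label list
(by default the uninformative database label "unidentified
*Synechococcus*") are skipped and the next-ranked hit takes their slot —
the only consistent treatment, since an excluded organism has no
frequency value to average. Organism counts over all queries are min–max
normalized to [0, 1]; if every organism is tied, all values are set to 1
(ties carry no discriminating signal, and 1 means "as common as the
commonest", avoiding spurious low-score regions). A protein's score is
the unweighted mean of its top hits' normalized frequencies; proteins
with fewer than `top_k` usable hits are averaged over what they have,
and proteins with none are *missing*, not zero — a no-hit protein is
evidence of foreignness, but scoring it 0 would conflate "no data" with
"hits rare organisms".

The per-window track is the unweighted mean score of the protein-coding
genes intersecting each window; a gene that straddles a window boundary
counts for every window it touches (no length or overlap weighting —
the simplest reading, and island calls are driven by whole-window means,
not single genes). Windows without scored genes are missing and can
never become island members.

## Island calling

A track value is anomalous when `|value − mean| > k_sd · SD` with
`k_sd` = 2 and the sample (n−1) standard deviation, both computed over
defined values only. The threshold is two-sided for both tracks, exactly
like mean ± 2·SD guide lines on a genome scan, even though the
biologically interesting score signal is the low side; a one-sided
option restricts the score mask accordingly. Windows anomalous on both
tracks are merged when their intervals overlap or abut — with
overlapping windows, flagged neighbors describe one contiguous anomalous
region — and each island reports its member windows and the CDS features
overlapping its interval. No minimum run length is imposed: a single
doubly-anomalous window is an island. Island count is non-increasing in
`k_sd`, and calls are invariant under reflecting either track about its
mean.

## Orthogroup repertoire statistics

Presence means copy count ≥ 1; orthogroup tables carry no e-value or
gene-fragment nuance, so none is modeled. Categories are tested in the
order core → ancestral → accessory, which makes them mutually exclusive
(a group in all free-living genomes is "core", never also "ancestral").
The ancestral proteome used for retention statistics is the union of the
core and picocyanobacterial-ancestral categories — all groups inferred
present in the picocyanobacterial ancestor; `include_core=False`
restricts it to the ancestral category alone for sensitivity analyses.
Retention bookkeeping asserts inclusion–exclusion
(`lost_both = |A| − retained_a − retained_b + shared`) and reports
percentages as missing rather than dividing by zero. Annotation is
tracked at orthogroup level (a group is annotated when it has a KEGG
orthology assignment). Marker selection for phylogenomic concatenation
takes groups single-copy in at least 99 % of scope genomes and never
multi-copy in any scope genome — a paralogous duplication anywhere
disqualifies the group, the conservative reading of "single-copy".

## Read recruitment

The alignment step itself is external; the module consumes its tabular
output. Row filters keep identity ≥ 99.0 % and alignment length ≥ 90
bases (both inclusive). "To a single genomic sequence" is enforced as
best-hit-per-read-per-genome by bitscore (ties: first occurrence), so a
read aligning twice to one genome is counted once; reads aligning to
multiple genomes count for each (recruitment is per-genome, as when each
metagenome is mapped against each reference separately). Masking drops
any read sharing ≥ 1 base with an rRNA or tRNA feature — the most
conservative reading of "mapped to" those regions; abutting half-open
intervals do not overlap. Subject coordinates arriving reversed
(minus-strand alignments) are normalized before the overlap test.
Per fraction, the report gives retained sums, the ratio to total reads
searched in that fraction, and each fraction's percentage of the
genome's retained reads (these sum to 100 whenever the genome recruited
at least one read). Subsampling reproduces the survey protocol: skip the
first 1,000 reads of a run, take the next five million.

## Synthetic data

Every generator is a pure function of its spec including a single
integer seed feeding one `numpy.random.default_rng` stream — identical
reruns are byte-identical, and no global random state is touched.

*Genomes.* Background and island sequences are drawn from order-0 or
order-3 Markov models. The order-3 tables are built from GC-weighted
base odds perturbed by context-specific log-normal noise
(`tetra_bias` × standard normal per (3-mer, base) cell, seeded by a
`key`), so islands differ from the background at the tetranucleotide
level proper, not merely in GC — the signal the PC1 track is built to
see. The standard island scene is a 500 kb genome (GC 0.55, bias 0.15)
with three 15 kb islands (GC 0.40, bias 1.0): strong but within the
range of real island/backbone composition contrasts. CDS features are
tiled end to end with mean length 900 bases and 100-base intergenic
gaps, matching typical cyanobacterial gene density.

*Hit tables.* Background genes draw their top-5 organisms from a common
pool by propensity (dominated by three close free-living relatives, as
in a real search against a broad database); genes whose midpoint lies in
a truth island draw only from a small rare-label set. This reproduces
the intended contrast — island windows' mean scores fall below every
background window — but not the messiness of real searches (partial
homology, shared domains, contaminated database labels).

*Ortholog matrices.* Two free-living clades (≥ 2 genomes each) plus
symbionts. Core groups are present everywhere free-living;
ancestral-extra groups are knocked out of exactly one free-living genome
(leaving both clades represented); accessory groups are confined to one
clade or to symbionts. Construction satisfies the category definitions
exactly, so classification must recover truth at 100 % — the test is of
the classifier's logic, not of noisy orthology inference, which is out
of scope. Symbiont retention is Bernoulli per category (defaults 0.95 /
0.6 / 0.1 for core / ancestral / accessory), mimicking the observed
pattern that reduction concentrates outside the core.

*Read sets.* Reads are sampled uniformly from source genomes according
to per-fraction mixing proportions (remainder = off-target, contributing
to reads searched but to no alignment), with per-base substitution
errors at rate 0.001 and a consistent pre-computed alignment table
(identity = 100·(1 − mismatches/length)), so recruitment runs without an
aligner. The default truth split (1 / 36 / 63 / 0 % across the four
fractions) mirrors a host-associated cyanobacterium concentrated in the
20–180 μm fraction; at 10,000 reads per fraction the recovered split is
within binomial sampling error (≈ 1 point) of truth. Real read sets add
quality variation, indels and mapping ambiguity that this generator does
not model, so passing tests demonstrate correct bookkeeping, not
robustness to alignment artifacts.

## Problem sizes and tolerances

Tests and the acceptance script run the island scene at 500 kb with
10 kb windows (55 windows), PCA oracle checks on 10 × 256 matrices,
recruitment at 10,000 reads per fraction, and classification on
190-group matrices — sizes chosen so the full suite completes in
seconds while every stage still exercises its signal-versus-noise
margins. Numerical comparisons against the eigendecomposition oracle use
a 1e-8 relative tolerance; PC1 centering is asserted to 1e-8 relative.
Island recovery counts a truth island as found when a call reaches
interval Jaccard ≥ 0.5 (window-union boundaries can overhang the truth
by up to one step, bounding the attainable Jaccard well above 0.5 for
15 kb islands).

## Known limitations

- Window PCA is per genome; tracks from different genomes are not on a
  common scale, so cross-genome comparisons should compare track
  *diversity*, not raw PC1 values.
- Organism labels are taken at face value (strain granularity, no
  taxonomy collapsing); label noise in real databases propagates
  directly into frequency scores.
- Circular topology is recorded but not exploited in windowing.
- The generators emulate the structure each analysis assumes, not
  realistic sequence evolution; they validate the pipeline's logic and
  arithmetic, not its behavior on every pathology of real data.
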