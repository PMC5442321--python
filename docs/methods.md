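# Methods

## Coordinate conventions

All internal coordinates are 0-based, half-open (BED convention); the
GTF reader converts its 1-based, closed intervals at the boundary. The
midpoint of a peak is the left median of its covered bases,
`floor((start + end − 1) / 2)`, so even-length peaks have a
deterministic, left-biased anchor. Strand is carried on intervals but
consulted only for the sign of TSS distances, never for overlap tests.

## Peak merging

Merging is single linkage over the pooled peaks of all datasets: two
peaks join the same merged region iff they share at least one base, and
chains (A–B overlap, B–C overlap) collapse transitively even when A and
C are disjoint. Because single linkage on intervals equals a sweep over
sorted starts, the implementation is O(n log n) and is cross-checked in
the tests against an explicit union-find over the all-pairs overlap
matrix. Bookended peaks (end == start) do **not** merge under the
default settings; a `gap` knob (merge gaps < g) and a `min_overlap`
knob (require ≥ k shared bases with the growing region) relax or
tighten the rule. Merged IDs are zero-padded ordinals assigned after
sorting by (chromosome, start), so they are stable across reruns and
input orderings. Provenance keeps, per declared dataset, the sorted
member peak IDs or an explicit ABSENT marker rendered `NA` — "no peak
was called here in that dataset" is a statement the downstream table
must preserve, not an empty string.

## Promoter/enhancer classification

The promoter window of a TSS is the closed ±w neighbourhood, stored
half-open as `[max(0, tss − w), tss + w + 1)`; w defaults to 2,000 bp.
A peak is class 1 (promoter) iff its span overlaps any window
(`proximity_mode: overlap`); the stricter variant testing only the peak
midpoint is available as `proximity_mode: midpoint`. The span-overlap
default is robust to wide peaks, whose edges can reach a promoter their
midpoint misses. Class is monotone in w by construction.

Every peak — promoter or enhancer — reports the gene whose TSS is
closest to the peak midpoint, because the table's closest-gene column
is descriptive, not an assignment for enhancers. Ties on |distance| are
broken by lexicographically smallest gene symbol, a declared convention
rather than an inference about any particular dataset. Genes with
several TSSs contribute one record per TSS (suffixed record IDs,
shared base symbol); classification uses all of them and reports the
base symbol. The signed distance is midpoint − TSS for `+` genes and
TSS − midpoint for `−` genes, so negative always means upstream; the
convention is stated in the output header.

## Loop-based enhancer assignment

A loop file (BEDPE) contributes anchor→target pairs. The anchor side is
configurable per file (`anchor_side: first|second`) because capture
Hi-C files are conventionally bait-first while plain Hi-C loop lists
are unordered. Anchors resolve to genes either through an explicit
semicolon-separated gene column (used verbatim when present) or by
overlap with the same ±w promoter windows used for classification —
one promoter definition across the whole pipeline. Loops resolving to
no gene are dropped and counted; trans contacts are kept and flagged.
An enhancer peak's assignment per interaction set is the sorted,
deduplicated union of anchor genes over all loops whose target overlaps
the peak by ≥ 1 bp; an empty union is `NA`. Sets are fully independent
columns: removing one never perturbs another, and removing a loop can
only shrink assignments.

## The interactome table

One row per merged peak, sorted by (chromosome, start): ID,
coordinates, per-dataset provenance, closest gene, signed distance,
class, and one gene column per interaction set. Two sentinels are
distinguished: `NA` means "looked, found nothing" (a dataset without a
peak at the region; an enhancer with no matching loop), while `.` in
the loop columns of promoter rows means "not applicable" — promoter
peaks are assigned by closest TSS, not by loops. A `strict_compat`
writer flag collapses `.` to `NA` for consumers that do not make the
distinction. The writer emits a commented header documenting column
semantics; write→read is the identity on every field and a second
write is byte-identical, which the tests enforce on randomized tables.

Gene-set queries search selected channels: `closest-promoter` matches
the closest gene of promoter-classified rows only (mirroring the
assignment rule — an enhancer's closest gene is not a regulatory
claim), and `interaction:<set>` matches that set's gene column on
enhancer rows. Matching is exact and case-sensitive by default
(`fold_case` folds it), and per-gene counts are distinct matching
records.

## ChIP-qPCR quantitation

Fraction of input is E^(mean Ct_input − mean Ct_ChIP) ×
input-dilution-factor, where E ∈ (1, 2] is the per-cycle amplification
efficiency (default 2.0, the ideal-doubling convention; settable per
amplicon in the Ct table). Replicates are averaged in Ct space
(arithmetic mean of Ct), the standard ΔCt practice; averaging template
quantities E^(−Ct) in linear space is available via a flag. Enrichment
is the ratio of the antibody's fraction to the IgG control's fraction
at the same locus. The formula is shift-invariant (adding a constant to
all Ct values cancels) and each extra cycle of ΔCt scales the fraction
by exactly E. The input dilution factor defaults to 1 and exists
because real protocols typically reserve a diluted input aliquot.

## Synthetic data and what it shows

The generator plants a genome whose geometry makes every truth
unambiguous: genes are spaced 20 kb apart (TSS jitter ±1 kb), so
promoter windows never collide; promoter peaks are placed in three
disjoint sub-slots inside a gene's window; enhancer peaks in four
slotted intergenic positions 4.7–8 kb from their gene's TSS — far
enough from every window that class 0 is guaranteed, close enough that
the owning gene is always the nearest. Slot margins (60 bp) absorb the
±10%-width boundary jitter applied when each dataset independently
re-emits a reference peak (probability = `dataset_concordance`, default
0.8, mirroring three partially concordant cell lines), so concordant
copies always re-merge into exactly one region and never touch a
neighbour. Loops are planted for a fraction of enhancers
(`frac_enhancers_looped`, default 0.6) with anchors inside the linked
gene's window and targets equal to the peak span shifted by at most
`loop_target_jitter` (100 bp < minimum peak width, so overlap is
guaranteed); surplus loops revisit chosen enhancers, producing
multi-gene cells. All randomness flows from one seed through spawned
sub-streams, so outputs are byte-reproducible.

Default scale — 2 chromosomes × 2 Mb, 50 genes, 200 reference peaks
(30% promoter), 3 datasets, 2 loop sets × 80 loops — keeps a full
pipeline run under a second while exercising every NA branch; a
documented `LARGE_PRESET` approaches the >10,000-promoter-anchor scale
of real capture designs. A `boundary_stress` mode instead plants one
peak per gene swept across the right window edge (offsets w−2 … w+3,
no emission jitter), verifying the half-open window arithmetic: a peak
starting at tss+w overlaps the window by exactly one base, at tss+w+1
by none.

Because placements are deliberately unambiguous, 100% recovery shows
the pipeline's *logic* is exact; it does not show robustness to
features of real data the generator omits: overlapping regulatory
elements, peaks straddling window edges (outside stress mode),
resolution mismatch between Hi-C bins and peaks, trans loops, copy
number, or mappability artefacts. A reference peak emitted by no
dataset (probability (1−c)^k ≈ 0.8% under defaults) legitimately never
reaches the output; recovery scoring compares only emitted peaks and
asserts the rest are absent.

## Numerical and degenerate-input choices

Empty intervals are rejected at construction; windows are clipped at
the chromosome origin; a chromosome with no genes yields class 0 with
gene and distance `NONE`; zero surviving loops is a warning, not an
error; duplicate peak IDs within a dataset and duplicate gene records
abort with the offenders listed; ID-set mismatches between pipeline
stages abort with the symmetric difference. The pipeline deletes
partial outputs on any stage failure and always writes a manifest with
input checksums, a config hash, and the stage counts, which must
satisfy promoters + enhancers = merged peaks and, per loop set,
linked + NA = enhancers.

## Known limitations

No peak calling, loop calling, or signal-weighted merging; no
isoform-expression weighting of TSS choice; no minimum overlap
fraction between peak and Hi-C bin beyond the configurable threshold;
gene symbols are treated as opaque strings (no alias resolution). The
query layer reports membership and counts only — the package computes
no enrichment statistics over gene sets.
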