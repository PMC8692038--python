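# Methods

This note documents the models, parameters and numerical choices behind
silkforge, and what the synthetic benchmarks do and do not demonstrate.

## Synthetic gene models and reads (`simgen`)

A synthetic spidroin is NTD + (repeat unit)×R + CTD. The terminal-domain
templates packaged in `_domains.py` are **synthetic** sequences constructed
once with a seeded generator: one 150 aa NTD and one 100 aa CTD base
sequence per clade (MaSp1, MaSp2, MaSp3, MaSp5, MiSp, Flag), with ~8%
per-family substitutions so that within-clade identity stays above 70%
while between-clade identity is near the random baseline. They emulate the
conservation structure of real spidroin terminal domains without
redistributing any natural sequence; MaSp4 deliberately carries a
MaSp2-clade NTD, and MiSp1B/C/D share the MiSp clade.

One repeat unit is built from the family's grammar — core motifs joined by
short glycine/serine-rich spacers, ending in the family's tail (poly-A run
of 5–8, poly-GA of 3–5 dimers, an explicit neutral-residue motif such as
VSVVSTTVS, or nothing) — and is rejected and resampled if it accidentally
contains another family's core motif or a forbidden alanine run. The unit
is reverse-translated once (uniform synonymous codons) and tiled R times at
the nucleotide level, emulating the near-identity of real spidroin repeats;
this nucleotide identity is what makes PWM extension enter a periodic
regime at the array rather than halting on repeat-to-repeat divergence.

Short reads: uniform start positions, random strand, i.i.d. substitutions,
constant Phred+33 quality; read count = round(coverage·L/read_len); paired
mode draws inserts from normal(μ, 0.1 μ). Long reads: gamma(shape 2)
lengths with the requested mean, truncated to the source, drawn until total
bases reach coverage·L; errors split 60/20/20 between substitutions,
insertions and deletions. No position-dependent quality model, chimeras or
duplicates are simulated. Coordinates are 0-based half-open; strands +/−.

## Seed-and-extend (`smoc`)

The de Bruijn graph counts canonical k-mers (lexicographic min of k-mer and
reverse complement; k odd so no k-mer is self-complementary; k-mers with N
skipped; nodes below `min_count` dropped; defaults k = 31, min_count = 2).
Unitigs are maximal non-branching paths over the implicit bidirected
adjacency, reported once in canonical orientation and sorted by (length
desc, lexicographic) for determinism. No tip or bubble cleaning is done: at
1% read error and 50× coverage, recurrent errors fragment unitigs, which is
why the default homology-seed score floor is 100 bits-like units — far
above the empirical random-contig null (~50) but low enough that a partial
domain hit on a fragmented contig still seeds extension. Seed hits come
from six-frame local alignment (BLOSUM62, gap open −10, extend −1) and are
reported in forward-strand contig coordinates.

Extension keeps the consensus in gene orientation; a C-terminal seed is
extended 5′ by reverse-complementing, extending 3′, and flipping back. Each
iteration re-anchors on the terminal anchor_k-mer (default 51 — large
enough that an anchor is effectively unique outside the repeat array),
collects the next base from every read containing the anchor in either
orientation, and appends the majority base only if depth ≥ min_depth (5)
and majority frequency ≥ min_frac (0.8); an exact tie halts with
`no_support` (curation favours precision over completion). The repeat
boundary test runs every 25 appended bases: position p is a boundary if
some period q ≤ period_max (150) matches ≥ 90% of positions across the
trailing window (300, ≥ 2·period_max); the smallest such p is reported.
Since the boundary can only be evaluated once the window fits, the
consensus deliberately overruns ~one window into the array before halting —
the overrun is still truth-identical for nucleotide-identical repeats.

## Long-read confirmation (`longread`)

Error correction is a deliberately minimal trusted-k-mer repair (not a
production corrector): a base whose covering k-mers (default k = 17) are
absent from the short-read spectrum is replaced by the unique substitution
restoring trusted k-mers, ambiguous or unrepairable bases are left alone.
It fixes isolated substitutions exactly and leaves most indels, which the
downstream alignment tolerates.

Candidate mapping prescreens reads for any shared seed 15-mer and then uses
an infix (semi-global) edit-distance alignment to locate the candidate and
score identity; coordinates are reported on the forward read strand. A
read supports a gene *full-length* when its N- and C-candidates map on the
same strand in order. Repeat counting tiles the inter-terminal segment
greedily left to right with prefix alignments of the unit (identity floor
0.75 against 8%-error corrected reads); the mode over full-length supports
is the reported architecture — this modal rule replaces what would
otherwise be a manual curation step and is an interpretation, not a claim
about how manual curation behaves.

## Reconstruction (`pipeline.reconstruct_gene`)

The terminal candidates overlap the repeat array from both sides but do not
meet, so the full gene is composed as: the N candidate, continued
periodically (period from the post-boundary autocorrelation) to the modal
repeat count less a small margin, then merged with the C candidate's
junction-spanning tail (one period plus the C-side domain) by exact
suffix/prefix overlap, choosing the placement closest to the expected
junction so the period-ambiguity of a purely repetitive overlap cannot
shift the count. Exact matching is intended for the zero-error closed loop;
noisy candidates may fail to merge, in which case reconstruction is
reported as failed rather than approximated.

## Catalogue (`catalogue`)

The grammar table (`data/grammar.tsv`) records, per family: clade, core
motifs, tail rule and explicit tail motifs. Cores and tails for MaSp1–5 are
the literally reported bark-spider motifs; the MiSp and Flag cores are
reconstructed stand-ins (marked in the notes column) because no literal
MiSp/Flag core is documented — MiSp subfamilies are therefore separated by
their documented tail rules (poly-A/GA for MiSp1B/D, poly-X for MiSp1C).
Motif matching is exact substring. Tails: explicit tail motifs are matched
as suffixes first; otherwise ≥3 tandem GA ⇒ poly_GA, a run of ≥4 A ⇒
poly_A, a suffix of ≥6 residues from {S,V,I,T,L,A} with no AAAA run ⇒
poly_X.

Repeat decomposition estimates the dominant period as the smallest lag
whose *windowed* self-match score (window max(2q, 20)) is within 0.05 of
the best — windowing keeps long unique flanks from diluting short arrays,
and preferring the smallest near-optimal lag resolves the q/2q/3q harmonic
ambiguity. The repetitive span is where a one-period rolling self-match
stays ≥ 0.7, with the start snapped past flank residues; fewer than two
full units counts as non-repetitive.

Family score = (fraction of units with ≥1 core motif) + 0.5 · (fraction of
units whose tail satisfies the rule); ties break by grammar-table order.
Nomenclature follows repeat content: an NTD clade that disagrees with the
motif winner sets a conflict flag rather than overriding (MaSp4 on a
MaSp2-clade NTD is consistent by construction, so no conflict). Units
recovered by period detection have arbitrary phase, so the pipeline scores
all cyclic rotations and keeps the best (`classify_family_rotation_
invariant`). CRP flagging uses a permissive cysteine threshold of 0.05 so
that a 10%-cysteine SpiCE-like protein is well inside the flagged region.

## Phylogeny (`phylo`)

Distances are p-distances (1 − identity over aligned non-gap columns) from
global pairwise alignment (BLOSUM62, open −10, extend −1); columns with a
gap in either sequence are excluded from numerator and denominator, and the
argument pair is ordered canonically before aligning so co-optimal
alignments cannot break symmetry. Poisson-type corrections are not applied.
Neighbor joining is the canonical Saitou–Nei algorithm with the lowest
label-index pair breaking Q-ties and negative branch lengths clamped to
zero with the deficit moved to the sibling edge. Bootstrap resampling draws
columns from a stacked pad-to-longest pseudo-alignment rather than a
progressive multiple alignment — a deliberate methodological substitution
that removes the external aligner; supports are the percentage of B
replicates containing each internal bipartition of the point-estimate tree
and are written as internal node labels in newick. On exactly additive
matrices NJ provably recovers the generating topology, which the test suite
verifies on random 6–10-taxon trees together with exact path-length
recovery.

## Profiles and fibre metrics

TPM is the textbook rate normalization (rate = count/length, scaled to sum
to 10⁶) on raw CDS lengths — effective-length modelling belongs to the
upstream quantifier, not this module; all-zero counts yield all-zero TPM
rather than an error. Expression ratios use a pseudocount (default 0.5)
for sparse silk-gene tables. Proteome shares are intensity-based.

Tensile summaries: toughness is the trapezoidal ∫σ dε converted at
1 GPa·strain = 1000 MJ m⁻³ (encoded once as `GPA_STRAIN_TO_MJ_M3`);
strength is max stress; strain at break is the last sample (×100); the
modulus is the free-intercept least-squares slope over strain ≤ 0.02 (the
initial linear region; the fit window is an implementation choice).
Crystallinity fits n user-initialized crystal Gaussians plus one broad halo
Gaussian by bounded nonlinear least squares; peak widths are capped at 2×
the widest initialization and the halo width lower-bounded just above that
cap, so the broad component cannot collapse onto a reflection;
crystallinity = peak area / (peak + halo area), which is invariant to
intensity rescaling. Profiles are assumed background-subtracted; an
explicit baseline term is out of scope. The number of crystal peaks is a
required user input.

## Benchmark sizes and limitations

The default closed-loop benchmark uses a single ~2.2 kb gene at 50× short /
15× long coverage, 20 replicates for noise robustness, 100 trees for the NJ
oracle, 50 fit replicates per crystallinity level, and 1000 tables for the
TPM property — sizes chosen so the whole suite runs in about a minute on
one CPU while keeping sampling error far from every asserted margin.

Passing these benchmarks shows the algorithms are correct under the stated
generative model; it does not show robustness to features the generator
omits: diverged (non-identical) repeat units would halt PWM extension with
`no_support` instead of a clean boundary, heterozygosity and paralogous
near-duplicates would create competing anchors, real Nanopore error
profiles are burstier than the i.i.d. model, and the packaged terminal
domains are synthetic stand-ins, so homology-seeding sensitivity on real
spidroin NTDs/CTDs is not measured here.
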