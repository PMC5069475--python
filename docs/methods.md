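# Methods

## Coordinates, strands, and the reference table

All coordinates are 1-based, fully inclusive (a tRNA at 1–65 is 65 bp);
the BED writer converts to 0-based half-open on output only. `J` is the
majority strand, `N` the minority strand; stored sequences are J-strand
and N-strand features are extracted as reverse complements. The genome is
treated as circular only at the junction level: the last-feature → first-
feature junction is reported with an `origin` flag and excluded from
overlap/spacer summaries, which also exclude junctions flanking the
control region (published spacer counts are quoted "in addition to the
control region"). Feature lengths are always recomputed from coordinates;
the printed size column of published tables is not trusted. Truncated
stop codons ("T-", "TA") are stored verbatim — completion to UAA by
polyadenylation is a transcript-level event — and their bases are trimmed
before any codon statistic so every CDS is in frame.

## Composition and skew

AT skew = (A−T)/(A+T), GC skew = (G−C)/(G+C), computed from base counts
with N excluded from numerator and denominator. A zero denominator yields
a flagged undefined value, never an exception. Whole-genome statistics
are reported on the J-strand; per-gene statistics on the coding strand.
Codon usage uses the invertebrate mitochondrial code (NCBI table 5),
drops terminal stop codons, and skips (but tallies) codons containing
ambiguous bases. Percentages are rounded only in reports.

## Nei–Gojobori Ka/Ks

Sites: for each codon, each of the nine single-nucleotide changes is
classified; changes that preserve the amino acid count toward synonymous
sites (divided by 3), changes producing a stop codon count as
nonsynonymous. Site totals are averaged over the two sequences, so
synonymous + nonsynonymous sites = 3 × codons exactly. Differences:
codons differing at k positions are averaged over all k! substitution
orders with equal weight; each step is synonymous iff the translation
(with '\*' for stops) is unchanged. Proportions pN, pS are corrected with
Jukes–Cantor, d = −¾ ln(1 − 4p/3), undefined (flagged, not raised) at
p ≥ ¾; the ratio is flagged undefined when Ks = 0 and never reported as
infinity. These stop-codon conventions match Biopython's NG86 routine,
which the test suite uses as an independent cross-check alongside an
exhaustive pathway-enumeration oracle. Codon alignment is the caller's
responsibility. The Ka/Ks–GC relationship is an ordinary least-squares
fit of per-gene Ka/Ks on G+C fraction.

## Tandem-repeat decomposition

For each candidate period p (default 5–250 standalone; 7–250 inside the
partitioner, see below) the detector computes the shifted self-match mask
m[i] = [seq[i] = seq[i+p]], merges true runs separated by at most 2
mismatches (unit variants produce isolated mismatch columns), and drops
terminal runs shorter than 3 so candidate spans start and end on solid
matches. A span of length L at period p is cut into ⌊L/p⌋ full units from
the span start plus a terminal partial of L mod p bases, which makes the
partial prefix-aligned to the consensus by construction. The consensus is
the per-column majority over full units (ties broken A<C<G<T); candidates
need n_full ≥ min_copies (a partial never counts toward the copy
minimum), mean unit-to-consensus identity ≥ 0.8, and a consensus whose
exact minimal period is ≥ the period floor (otherwise a microsatellite
masquerades as a longer-period array).

Period minimality: candidates covering the same locus (≥80% reciprocal
overlap) form a group; the smallest period wins among candidates whose
identity is within 0.02 of the group's best **or** at least
min(best, 0.9). The second clause exists because consensus identity
inflates mechanically at period multiples — fewer units vote per column,
so an incidental longer-range regularity of the unit arrangement can
out-score the true period by more than the tolerance; a strongly
supported short period must not lose to it. Remaining cross-locus
conflicts resolve longest-array-first.

Unit typing: variable sites are unit columns where at least two residues
each occur in ≥ 2 units (`min_minor_count`); types are the residue
combinations at those sites, numbered by descending copy count (ties by
first occurrence). A combination seen fewer than `min_minor_count` times
is treated as a point mutation and merged into the nearest type by
Hamming distance. The terminal partial is labeled by best prefix match
against the type templates (ties to the lowest type id) and counted
separately from the full-unit counts. Adjacency reports the transition
count matrix over consecutive full units; the rule "every X followed by
Y" requires X to occur, to never be terminal, and to have only Y
successors.

## Motif scanners and partitioning

Homopolymers are maximal single-base runs (default minimum 8 bp, the
length of the poly-C and poly-A tracts in the study system).
Microsatellites are maximal perfect tandem runs of unit 2–6 reported at
the minimal period (so an A-run is never a period-2 hit) with, inside the
partitioner, at least 3 copies and 10 bp. Content blocks are unions of
sliding windows (default 20 bp) meeting an A+T (0.9) or G+C (0.25)
threshold, merged when coverage abuts, with block content recomputed on
the merged slice. Hairpins are inverted repeats: two equal arms flanking
a 3–12 bp loop, pairing reverse-complementarily with ≤ 1 mispair,
innermost and outermost pairs required true; hits record whether a TATA
element ends within 10 bp upstream of the 5′ arm, and nested hits are
suppressed.

The partitioner claims positions by fixed precedence — tandem array >
hairpin > microsatellite > poly tract > GC block > AT block — trimming
lower-tier hits to unclaimed positions and discarding block fragments
under 10 bp. Inside the partitioner the array detector's period floor is
raised to 7 (= microsatellite max unit + 1) so that (AATTT)₃ is labeled a
microsatellite, matching how control-region maps draw it. The hairpin
search runs only downstream of the detected tandem array (stem-loops
involved in replication origin sit just downstream of the array in these
genomes); with no array there is no search region, overridable in the
config — a generic whole-sequence hairpin scan would label some inverted
repeat in almost any A+T-rich sequence. Unlabeled interior gaps become
linkers (gaps ≤ 4 bp are absorbed into the preceding segment), edge gaps
are `unassigned`, and a sequence with no recognized feature is a single
unassigned segment. Segments always tile the input; this is asserted on
every run.

## Slippage simulation

State is the ordered list of unit-type labels; nucleotide-level mutation
is out of scope. Per replication round, duplication and deletion event
counts are Poisson(dup_rate) and Poisson(del_rate) — defaults 0.05 and
0.02 per replication, encoding the empirical duplication > deletion
asymmetry; rates are free parameters with no claimed physical calibration.
Each event picks a uniform start unit and a geometric block length
(parameter `block_p`, truncated at the array end); duplications insert an
adjacent copy of the block, deletions remove it. With chimeras enabled, a
deletion of ≥ 2 units whose 5′ breakpoint is a Type II unit and whose 3′
breakpoint is a downstream Type I unit instead leaves one Type IV unit —
the minimal formalization of the mispairing mechanism proposed for the
rare fourth variant; which variable-site residues the chimera carries is
not modeled, only the label. Extinction (a deletion that would empty the
array) truncates the trajectory with a flag rather than resampling, so
ensembles stay unbiased. Trajectories are pure functions of
(config, seed) and the event log replays to every recorded state; both
properties are asserted in tests. At dup_rate = del_rate with unit
blocks, array length is a martingale, which the tests verify at 10,000
trajectories within three Monte-Carlo standard errors.

## tRNA conservation

A column is *identical* iff every row carries the same non-gap residue —
a gapped column can never be identical; *ge80* iff the modal non-gap
residue covers ≥ 80% of rows (gap rows in the denominator); else
*variable*. INP% = 100 × identical columns / alignment length; the
ungapped-column denominator is available as an option since published
figures do not state which is used. Region conservation recomputes INP%
over columns sharing a structure label (acceptor stem, DHU arm, …),
omitting absent regions. The strand contrast reports mean INP% per strand
class with per-family values and no significance test (a descriptive
contrast). The center-star aligner (match +1, mismatch −1, gap −2,
first-index center on ties, deterministic traceback) is convenience
plumbing for unaligned input, not a replacement for a curated alignment.

## Synthetic data generators

Every generator is a pure function of (config, seed), and each output is
designed to be recognized by its consuming analysis module — the
round-trip is the package's core testing mechanism.

**Repeat array.** Unit templates are an 18-mer family: the 13-bp Type I
prefix GAATTAGATTAAA extended by 5 fixed synthetic bases, with variable
sites at unit positions 5 and 15 and residue combinations chosen so that
Type IV = 5′ half of Type II joined to 3′ half of Type I, consistent with
its chimeric origin. The emitted sequences therefore share the published
architecture, not the deposited sequence. Default copy counts are
18/15/15/4 (52 full units) plus the 13-bp terminal partial, giving
52 × 18 + 13 = 949 bp. Arrangement rules (array starts with Type I, every
Type III sits in a II–III–I chain, every Type IV immediately precedes a
Type II, terminal partial is a Type I prefix) admit a unique block
decomposition — [IV II III I], [II III I], [I] — so uniform sampling over
block orders samples valid arrangements uniformly; infeasible counts
raise an error naming the violated rule. Under the full rule set the
Type II and Type III counts must be equal.

**Control region.** Elements are concatenated in the published order: a
321-bp block of 32.1% G+C, (AATTT)₃, 8-bp poly-C, (TA)₅, a 103-bp block
of 90.3% A+T, 8-bp poly-A, a 34-bp linker, the array, a second 34-bp
linker, TATA, and a 12-bp-stem / 8-bp-loop hairpin (1,518 bp in total).
Content blocks are built from per-tile quotas (e.g. every aligned 20-bp
tile of the GC block carries 6–7 G/C) so that sliding windows cannot dip
below the scanners' thresholds inside a block; linkers use fixed G/C slot
masks guaranteeing every 20-bp window holds 3–4 G/C (fails both content
scanners) while boundaries adjacent to all-A/T features accumulate 3
slots within 9 bp (so content-window creep across a boundary stays below
the minimum reported fragment). Fillers are additionally
rejection-sampled against the actual scanners, and the assembly is
validated to contain exactly one detectable array at the planted period.
The base flanking each array end is constrained not to extend the array's
periodicity, which keeps detected boundaries exact.

**Mitogenome.** Gene bodies are drawn per-base from coding-strand
composition targets (A+T content, AT skew, GC skew), reverse-complemented
onto the J-strand for N-strand genes; consequently whole-genome J-strand
skew is diluted toward zero by the N-strand genes, and skew-recovery
checks read the coding strand. The ATGATAA overlap heptamer is planted on
the J-strand at the ATP8/ATP6 and ND4/ND4L junctions; annotated start and
(possibly truncated) stop codons are planted where motifs do not already
occupy the positions. Internal stop codons in the random gene bodies are
not purged — synthetic codon-usage tables therefore contain stop codons
that a real gene would lack. The control region is generated as above and
padded to the annotated 1,853-bp slot with neutral filler (validated to
add no spurious array).

**Family alignments and CDS pairs.** Alignment columns are identical with
a stated probability (optionally per structure region); non-identical
columns draw rows independently, so measured INP% is binomial around the
target up to a vanishing accidental-identity term. CDS pairs apply at
most one substitution per codon — synonymous with probability `syn_prob`,
else nonsynonymous with `nonsyn_prob` — over ancestors sampled from
codons that have both kinds of non-stop neighbors, optionally GC-biased
via a per-codon weight; with single hits per codon the NG86 difference
counts recover the planted counts exactly, and rate recovery is tested
within three binomial standard errors at 500 codons.

**What the generators do not emulate.** Real control regions carry indels
and imperfect repeat copies (the decomposer is exact-match based, not an
indel-tolerant aligner in the TRF sense); real tRNA families evolve on a
phylogeny (columns here are independent, with no tree and no indels); and
synthetic whole-genome composition percentages, codon usage, INP% values
and Ka/Ks–GC R² are stand-ins — the published values for those quantities
depend on the real deposit and related mitogenomes, are cited in the
package only as reference behavior, and are not test targets. Passing
tests demonstrate correctness of the algorithms on data matching the
stated architecture, not re-measurement of the deposit.

## Problem sizes used in tests and scripts

The acceptance suite runs the decomposer-exactness property at 25 random
(p, c) configurations, the NG86-vs-oracle comparison at 80 random codon
pairs, slippage neutrality at 10,000 trajectories of 50 replications, and
parameter recovery at 500 codons; the analysis scripts use 1,000
slippage trajectories and 12 synthetic tRNA families of 14 taxa. The
whole suite completes in well under a minute on one CPU.
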