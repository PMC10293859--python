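# Methods

This note documents the models and procedures implemented in `tn7kit`, the
parameters that matter, the design choices made where the design was open,
and what the synthetic-data generators do and do not emulate.

## Coordinates and conventions

All coordinates are 0-based half-open internally; GFF3 output converts to
1-based inclusive. Intergenic gaps are measured end-of-upstream-feature to
start-of-downstream-feature, so overlapping features have a negative gap.
Sequence comparison throughout is the Hamming metric (substitutions only):
every threshold in the pipeline ("up to 2 mismatches", "3 mismatches
maximum") counts base substitutions, which is why the read simulator uses a
substitution-only error model — indel realism would change the contract the
filters are defined on.

## Locus discovery

Hits are protein-profile matches placed on genes. Per contig, hits are
clustered by single linkage on the inter-hit interval gap with threshold
`max_gap = 20,000` bp ("no further than 20 kb" ⇒ gap ≤ 20,000). Operons are
maximal runs of codirectional genes in which each adjacent gap is strictly
less than `operon_gap = 50` bp; overlapping codirectional genes are
operonized. Loci are accepted when all three criteria hold:

1. **distinct components** — ≥ 2 hit genes covering ≥ 2 distinct component
   classes. A TnsA-TnsB fusion gene (class `TnsAB`) contributes both
   activities, so a fusion plus any second component passes.
2. **operonized pair** — ≥ 2 hit genes share an operon. When a gene table is
   supplied, operons are called over *all* annotated genes in the locus
   span, so a non-hit cargo gene can glue (or a strand switch can break) an
   operon chain between hits.
3. **boundary** — every hit gene lies ≥ `edge_margin = 3,000` bp from both
   contig ends. The rule's stated purpose is to remove elements truncated
   by contig boundaries, which requires genes to be *far from* the ends;
   the opposite (literal) polarity is available as
   `edge_rule="require_near"` for comparison.

Histogram accounting over the selector-multiplicity histogram is exact
integer arithmetic: tandem loci = Σ_{m≥2} n_m and total selectors =
Σ_m m·n_m.

## Selector association

Selector-to-TnsC assignment resolves the ambiguity created by co-occurring
transposons and TnsC-like cargo ATPases. For a representative TnsC, every
TniQ/TnsD within the vicinity window is examined: if no other TnsC lies in
the vicinity, all are assigned to the representative; otherwise a selector
moves to the closest strictly-closer TnsC *that is operonized with a TnsB*
(evidence of a real transposase operon) and is retained by the
representative otherwise. Distance between genes is the minimal interval
distance (0 when overlapping); exact distance ties favour the
representative, for stability. The vicinity defaults to 50,000 bp — the
same window used for neighborhood annotation, which is the only window the
procedure names; it is configurable.

Size classification is a single threshold: length strictly greater than
400 aa ⇒ TnsD-like (direct target binding), otherwise TniQ-like (adaptor).
Neighborhood annotation labels genes within 50 kb of the central TnsC; cas
labels (Cas effector, Cas6) require a profile score of at least 25, and
sub-threshold cas hits are labeled `other`. Partner-candidate extraction
returns genes sharing an operon with a selector that are not themselves any
core Tn7 component — the signature by which the TnsF family of target
selectors was recognised.

## End detection

Transposon ends carry compact arrays of short repeats. The finder slides a
12-nt window over a flank (default 1,000 bp each side of the component-gene
span) and grows clusters by consensus closure: membership is all windows
within `max_mismatches = 3` of the consensus (direct or reverse-complement
orientation), and the consensus is the per-column majority of the oriented
members (ties break to the alphabetically smallest base), iterated to
stability. Two constraints keep the definition meaningful on real-size
flanks: members must form a positional chain (consecutive occurrence starts
≤ 60 bp apart) containing the seed window, and the seed must remain a
member. Without them, chance matches — a random 12-mer lies within 3
mismatches of a given consensus with probability ≈ 4·10⁻⁴, i.e. several
times per kilobase — accrete into spurious high-copy clusters. Overlapping
member windows collapse to the copy with fewest mismatches, clusters need
≥ `min_copies = 2` collapsed occurrences, and survivors are ranked by copy
number then total mismatches.

End calling pairs one cluster from each flank, preferring pairs whose
consensus units agree between sides (directly or inverted); if no pair
agrees within the mismatch budget there are no canonical ends and no call
is made — absence is reported honestly. Boundaries start at the outermost
occurrence edges (the second-outermost is also tried, tolerating one chance
window chained onto an array edge) and are then refined by the TSD: both
boundaries slide jointly by up to ±3 bp and the position exposing the
longest *strictly adjacent* exact duplication wins, with two guards — a
candidate TSD that is a substring of the consensus unit is array content,
not target sequence, and is vetoed; and the terminal windows just inside
the two boundaries must agree with each other (directly or inverted), which
is true only in the correct repeat frame. TSD search is exact-match only
(lengths 3–12): a TSD is two copies of the same target site, and mismatches
indicate a wrong boundary.

Two properties of this detector are worth knowing. First, at the permissive
published thresholds (12 nt / ≤ 3 mismatches / ≥ 2 copies), purely random
1-kb flanks contain qualifying chance clusters often enough that about
two-thirds of random sequences produce a (meaningless) call; requiring 3
copies per end removes essentially all such false calls (0/30 in the test
suite's measurement). Second, with only 2–3 repeat copies per end the
reading frame of the unit can be *mathematically ambiguous*: when a planted
mutation falls on the unit's edge column and the flanking bases coincide
across copies and sides, a frame shifted by 1 bp explains the data as well
as the true frame and carries an equally long shifted "TSD". Measured over
100 planted genomes this costs ~2% of joint end+TSD recoveries (98/100);
it is an information limit of short low-copy arrays, not a bug to patch.

## Duplication test

`patristic_distance` sums branch lengths along the unique leaf-to-leaf
path (missing branch lengths are an error, never silently 1; zero-length
branches are allowed). `dual_pair_duplication_test` compares the
within-pair distances of labeled paralog pairs against `n_null = 1000`
random couples drawn uniformly from the leaves outside the pair-member set
(two distinct members per couple; couples may repeat across draws). The
test is Welch's two-sample t-test by default (`equal_var=True` switches to
pooled variance); the p-value is two-sided, and the direction — pairs
closer than random, as expected under repeated in-situ duplication — is
carried by the sign of the t statistic. Results are fully determined by the
seed.

Calibration is evaluated at the study design used for the power analysis:
200-leaf trees, 20 pairs, 1,000 null couples. Under the null scenario
(pairs are random couples) the measured rejection rate at α = 0.05 is
0.05–0.07 across seed blocks — slightly anti-conservative because patristic
distances within one tree are correlated and because the null couples are
restricted to non-pair leaves, whose mean pairwise distance differs
randomly from the whole-tree mean. The effect grows on smaller trees
(≈ 0.09 at 100 leaves). Under the in-situ scenario with tight cherries
(pair branch scale 0.01) power is ≥ 0.95. The published full-scale analysis
(4,916 leaves) is far outside desk scale; this calibration characterises
the procedure instead.

The motif-column gap filter retains a sequence only if it has a residue at
every anchor column (e.g. the zinc-finger CxxC positions for TniQ, Walker
A/B for TnsC); it is the alignment QC applied before tree building.

## Insertion counting

`hamming_find` reports every window of a read within an anchor's mismatch
budget, on the forward strand and (by default) the reverse complement —
long reads arrive in both orientations, and both-strand search keeps
classification orientation-invariant. QC keeps reads strictly longer than
2,500 bp with mean Phred strictly above 7 (the mean over the read is the
standard long-read quality summary).

Classification uses two anchor tiers: three 25-bp filter anchors (target
fragment, left end, right end; ≤ 2 mismatches each) discard low-quality and
contaminating reads, then four 30-bp anchors decide structure. Reads with
the downstream target edge (1) and the distal end (2) are insertion
candidates; candidates lacking the upstream target edge (3) or the cargo
anchor (4) are non-simple; otherwise the distance between anchors (3) and
(4) is compared to the expected simple-insertion spacing with a ±50 bp
tolerance (configurable and reported) — a co-integrate retains donor
backbone between the end and the cargo, displacing this distance by the
backbone length. Reads passing the filter but lacking both junction anchors
do not span the junction and stay unclassified; unclassified reads are
excluded from the simple-fraction denominator. The 2-mismatch budget is
stated for the 25-bp filter anchors and adopted for the 30-bp anchors as
well (configurable). The four AjTn6022 30-bp anchors are shipped verbatim
as `AJ_TN6022_CLASS_ANCHORS`.

TTISS: R1 reads beginning with the terminal transposon end are trimmed of
it; alignments are kept when the aligned length equals the expected trimmed
length exactly (16 bp for AjTn6022 after the 29-bp end trim; 39 bp for
ZooTsy after 36 bp) and the SAM flag is 99 or 147 (proper-pair
orientation). A kept record is on-target when its mapped position falls in
a configured site interval. Both read tallies and unique-(position, strand)
tallies are reported per site. ddPCR insertion frequency is
inserts/template × 100, in percent.

## Synthetic data

The generators produce every input with planted truth; identical seeds give
byte-identical outputs.

**Genomes.** Contigs are uniform random DNA (default 5 contigs × 200 kb)
carrying 5 planted loci and 30 decoys, separated by > 20 kb so each forms
its own locus under aggregation. A planted locus is: a 5-bp TSD, a terminal
array of three 12-nt repeat copies (8-bp spacers; copies after the first
carry 0–2 substitutions; one exact copy sits at each boundary), component
genes (TnsA, TnsB, TnsC, TniQ/TnsD; 900–1,800 bp; intergenic gaps 5–45 bp,
all codirectional, hence operonized) with one non-component cargo gene
inside the run (a partner-selector candidate), a mirrored right array, and
the TSD again. Decoys come in three kinds, each built to violate exactly
one selection criterion and satisfy the other two: `single_component` (an
operonized TnsC pair — one class), `no_operon` (distinct classes with a
≥ 60 bp gap or antisense arrangement), and `edge` (a valid pair pinned
within 3 kb of a contig end; at most two per contig). Infeasible layouts
fail loudly with no partial output.

**Junction reads.** A fixed plasmid-like template (seeded separately from
the read batch, since it models the construct) embeds the four verbatim
classification anchors at their natural positions; filter anchors are 25-bp
cuts of the target/LE/RE regions. Simple reads copy
target-up|LE|cargo|RE|target-down; co-integrate-like reads retain 2 kb of
donor backbone between the left end and the cargo, displacing the
(3)→(4) spacing well beyond the tolerance. Each read is padded to a length
drawn from 3–6 kb, reverse-complemented with probability ½, and subjected
to seeded substitution noise; base qualities are constant Q12. The
generator does not emulate real nanopore error profiles (no indels, no
homopolymer effects) or empirically fitted read-length distributions —
passing tests therefore demonstrate the classification logic and its
mismatch contracts, not robustness to real nanopore noise.

**TTISS.** `round(frac_on_target · n)` pairs are planted inside on-target
intervals, the rest uniformly elsewhere; R1 is the terminal end plus the
insertion-site sequence. A toy mapper emits one alignment per pair at the
planted position (flag 99 forward / 147 reverse) — with planted positions
an exact mapper is the appropriate oracle, and running a real aligner is
out of scope. Optional rejected records (wrong flag, wrong length, missing
terminal end) exercise the filters.

**Trees.** Random binary topologies by sequential random joins with
exponential branch lengths (mean 0.5 — positive, scale-controllable, the
standard simple choice). `in_situ_duplication` replaces random leaves with
cherries whose branch lengths have mean `pair_branch_scale`, so within-pair
distances vanish as the scale → 0; `single_origin` builds two
topology-identical clades holding first and second members respectively;
`null_random` pairs disjoint random leaves on a plain tree.

## Problem sizes

The shipped verification uses: 5 genomes × (5 loci + 30 decoys) for locus
discovery; 50 single-locus genomes for end recovery; 1,000 null and 200
in-situ replicates (200 leaves, 20 pairs, 1,000 null couples each) for the
duplication test; 500–4,000 reads for insertion counting. These sizes give
sampling errors comfortably below the decision thresholds while keeping a
full run in minutes on one CPU.

## Known limitations

* The 2-copy repeat rule is not specific on random sequence (see End
  detection); interpret calls on elements without strong arrays with care.
* Repeat-frame ambiguity bounds end/TSD recovery at ≈ 98% even at zero
  sequencing noise.
* The duplication test is mildly anti-conservative at small tree sizes;
  its null calibration, not a nominal α, should be quoted.
* The manual local-alignment boundary refinement of the original procedure
  is approximated by the ±3 bp TSD-guided slide; boundaries are therefore
  reported to ±2 bp, not to the base.
* Profile searches (hmmsearch etc.), read alignment (BWA), clustering
  (MMseqs2) and tree building (FastTree) are upstream tools whose outputs
  this package consumes; it does not run them.
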