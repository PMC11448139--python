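# Methods

## System and scope

The package models the computational layer of an ICE (integrative and
conjugative element) study: an element integrated in a host chromosome
between two identical direct repeats (`attL`/`attR`; 9-bp `GATTTTAAG` in
ICE_KKS102_Tn4677), excised by site-specific recombination into an
attP-bearing circle plus an attB-bearing chromosome, transferred from an
oriT region, and regulated by a LysR-type activator (TraR) binding
T-N11-A sites. Wet-lab quantities (transfer frequencies, measured qRT-PCR
fold changes) are measurements, not model outputs; everything here is
sequence arithmetic, scanning, counting and normalisation.

Coordinates are 1-based inclusive everywhere, matching GenBank usage.

## Paired-read mapping

Each read contributes its initial k-mer (default k = 21) as a seed; seeds
are matched at 100 % identity against an exact hash index holding both
strands in forward coordinates. A candidate placement pairs a forward-strand
hit of one seed with a reverse-strand hit of the other, facing inward; its
end-to-end distance is the inclusive span from the leftmost to the rightmost
seed base. Placements outside [20, 2000] bp are discarded, the
minimum-distance survivor is chosen, and a tie at the minimum is classified
`ambiguous` and excluded from counting — conservative, since a tied pair has
no unique origin. Two interpretation choices were open and are resolved as
follows:

* *Orientation.* Seeds must land on opposite strands facing inward (a
  proper pair). This matches paired-end chemistry and prevents nonsense
  spans. A pair whose hits admit no such pairing is `unmapped` (it cannot be
  placed at all), while `distance_violation` is reserved for pairs with
  orientation-valid placements that all fall outside the window.
* *Feature attribution.* A mapped span increments every gene it overlaps by
  ≥ 1 bp (whole counts, not fractional). Expression comparisons normalise to
  a reference gene first, so uniform attribution choices cancel.

Seeds containing N are unmappable; reads shorter than k are rejected.

## Motif and promoter scanning

The T-N11-A scanner reports every position pair (t, t+12) holding T and A
whose flanking arms — arm_len bases ending at the T and starting at the A,
i.e. the conserved bases are the innermost arm bases — reverse-complement
with at most `max_arm_mismatch` mismatches (default arm_len 5, mismatch 1;
the packaged sites need arm_len 6 with budgets 0–3). T-N11-A is its own
reverse complement, so reverse-strand scanning only re-finds forward hits;
duplicates are collapsed keeping the forward call. Similarity and half-site
searches are Hamming-only (no indels), both strands.

Promoter calls score every −35/−10 hexamer pair with a 15–21-bp spacer by an
additive position-weight table for TTGACA/TATAAT derived from compiled
E. coli sigma-70 promoter alignments (consensus base scored by its
conservation percentage, alternatives uniformly with the remainder;
versioned as `ec-sigma70-1`), normalised so a consensus box scores 1.0, with
a linear penalty of 0.02 per bp of deviation from the optimal 17-bp spacer.
Only score *ordering* is load-bearing: calls are guaranteed
consensus-maximal and spacer-bounded, and no analysis asserts absolute
score values. The "immediately upstream" architecture flag defaults to a
≤ 5-bp gap between site end and −35 start, reflecting sites abutting the
box.

## oriT dissection

Inverted repeats are found by extending arms outward from every candidate
loop placement (loop ≤ max_loop) while the mismatch budget allows, trimming
so maximal arms never end on a mismatch, and suppressing hits contained in a
longer hit with no more mismatches. Conservation across homologous regions
is scored without an aligner: each reference window of fixed length
(default 20 bp) takes, per homolog, the best Hamming identity over all
same-length homolog windows on either strand; the window maximising the
mean wins, leftmost on ties. This is an alignment-free stand-in for reading
a column block off a multiple alignment, chosen because it is exactly
checkable against a brute-force oracle.

Deletion constructs are classified from the features their retained
intervals fully contain: functional ⇔ conserved 20-mer AND REPT1 retained;
attenuated when those are retained but the REPT2 region is lost (transfer
detectable but roughly two orders of magnitude lower); nonfunctional
otherwise. The packaged deletion series encodes the published construct
boundaries (left deletions functional through 261 and lost at 298, right
deletions functional through 393, REPT2 loss attenuating, REPT1 loss
abolishing, minimal construct 261–318); its feature coordinates are
synthetic stand-ins consistent with those endpoints because the reference
figure is not machine-readable, and the fixture sequence
(`make_orit_region`) is likewise a labelled synthetic stand-in carrying real
palindromes and a planted conserved 20-mer at those coordinates. The
essential region is the intersection of all transfer-competent constructs'
retained intervals (an error if empty or discontiguous), with a warning if
a nonfunctional construct fully contains it. Note the published minimal
construct spans 261–318 and therefore lacks REPT2; under this rule it is
classed attenuated, which maps to the published binary label
"transfer detectable".

## Excision model

`excise` places the crossover at the repeat's left edge: the circle is the
slice from attL start to attR start − 1 (one repeat copy at the attP
junction, rotated to position 1), the chromosome keeps the other copy at
attB. Because the copies are identical any consistent crossover convention
yields identical molecules; the convention only fixes which copy travels.
Total length is conserved exactly, `integrate` is the inverse, and
round-trips are byte-identical. Circular molecules are stored linearly with
the junction-first rotation plus a `circular` flag; primer and fragment
searches on circles scan `seq + seq[:max_product]` and deduplicate.

qPCR is modelled at the relative-copy level rather than Cq. Measured copies
are divided by an internal-standard target (primers amplifying both element
forms, `set_c`) at the same timepoint — making the panel invariant to
per-sample DNA amount — then expressed relative to the first timepoint,
which is 1 by construction. A zero at the first timepoint is an error
(fold change undefined) rather than a silent drop.

## Synthetic data

The generator emulates the study's input structures: a host chromosome with
the element inserted between two repeat copies, genes tiled inside
(xis, int, traI, traG, traR) and outside (rrn, hostA) the element; planted
motifs recorded as features; error-free paired reads (optional per-base
substitution rate, default 0, for mapper-loss experiments) with fragment
lengths from Normal(insert_mean = 300, insert_sd = 50) truncated to
[read_length, template length] — generic short-insert library values, since
the real library metrics are unpublished — and a qPCR panel with per-sample
scale factors and multiplicative lognormal noise (CV 0.1).

Background sequence for integrated genomes is generated so that every
k-mer of the boundary-repeat length occurs at most once (a greedy
unique-k-mer walk), and the assembly is verified until the att pair is the
genome's unique longest direct repeat; this makes boundary-repeat detection
a well-posed recovery problem instead of a race against chance repeats. The
construction requires 4^len(repeat) ≥ 8 × genome length and raises
otherwise. Fragment sources are drawn with probability proportional to
template weight × expression weight of a feature, so programmed expression
ratios are exactly the sampling odds and are recoverable to binomial error.

Determinism: one root seed; child generators are spawned per operation
(host, element, reads, panel) in that fixed order, so identical configs give
byte-identical FASTA/FASTQ output.

What the generator does *not* emulate: empirical base-quality or error
profiles, adapter read-through, GC or coverage bias, repeat families beyond
the planted ones, or amplification-efficiency differences between qPCR
targets. Passing tests therefore demonstrate algorithmic correctness on
structurally faithful inputs, not robustness to real sequencing artefacts.

## Problem sizes and verification

Default simulated genomes are 8 kb (5 kb host + 3 kb element) and the toy
worked example 1,318 bp; mapper cross-validation uses one hundred random
genomes of 1.5–10 kb with 60 pairs each, against an independent brute-force
mapper that enumerates seed placements by substring scanning; expression
recovery uses 20,000 pairs per condition. All scanners are checked against
naive sliding-window oracles on sequences of a few kilobases, and
inverted-repeat detection against an exhaustive arm-pair scan.

## Known limitations

* The real 463-bp intergenic sequence and the real SM-series primers are
  not redistributable here; fixtures are labelled synthetic stand-ins with
  the published interval structure. The analyzers accept real FASTA input
  (e.g. the host genome record) where available.
* Exact seeding means a single substitution in a seed unmaps the pair —
  faithful to the mapping strategy modelled, not a general-purpose aligner.
* `essential_region` assumes a single contiguous essential interval, which
  holds for nested deletion series but not for two-part dependencies.
* The promoter score is a homology heuristic; it ranks candidate boxes and
  is not calibrated to promoter strength.
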