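"""Exact-seed paired-read mapping and transcript counting.

The mapping strategy re-implemented here anchors each read of a pair by its
initial 21-mer, requires 100% seed identity, keeps only inward-facing
opposite-strand placements with an end-to-end distance (outermost base to
outermost base of the two seeds, inclusive) between 20 and 2,000 bp, and
selects the shortest distance when several placements qualify. The genomic
range spanned by a mapped pair is counted as a transcript: it increments
every gene feature it overlaps by at least one base. Expression is compared
between conditions after normalising each gene to a reference gene
(the rRNA operon, *rrn*, in the original study).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from math import inf

import pandas as pd

from .core import Feature, GenomeRecord, revcomp

DEFAULT_K = 21
DEFAULT_MIN_DIST = 20
DEFAULT_MAX_DIST = 2000


@dataclass(frozen=True)
class ReadPair:
    id: str
    seq1: str
    seq2: str


@dataclass
class KmerIndex:
    """Exact k-mer lookup over both strands of one genome.

    ``lookup`` maps a k-mer to ``(position, strand)`` hits; the position is
    always the 1-based forward-strand start of the k bases covered, and
    strand '-' means the k-mer occurs as the reverse complement of that
    forward window. Windows containing N are never indexed, and query seeds
    containing N never hit.
    """

    k: int
    genome_id: str
    genome_len: int
    lookup: dict = field(default_factory=dict, repr=False)

    def query(self, seed: str) -> list[tuple[int, str]]:
        if len(seed) != self.k or "N" in seed:
            return []
        return self.lookup.get(seed, [])


def build_index(genome: GenomeRecord | str, k: int = DEFAULT_K) -> KmerIndex:
    seq = genome.seq if isinstance(genome, GenomeRecord) else genome.upper()
    gid = genome.id if isinstance(genome, GenomeRecord) else "genome"
    if len(seq) < k:
        raise ValueError(f"genome length {len(seq)} shorter than seed length {k}")
    lookup: dict[str, list[tuple[int, str]]] = defaultdict(list)
    for i in range(len(seq) - k + 1):
        w = seq[i : i + k]
        if "N" in w:
            continue
        lookup[w].append((i + 1, "+"))
        lookup[revcomp(w)].append((i + 1, "-"))
    return KmerIndex(k=k, genome_id=gid, genome_len=len(seq), lookup=dict(lookup))


@dataclass(frozen=True)
class MappingResult:
    pair_id: str
    status: str  # mapped | unmapped | ambiguous | distance_violation
    span_start: int | None = None
    span_end: int | None = None
    distance: int | None = None
    n_candidates: int = 0


def map_pair(
    index: KmerIndex,
    pair: ReadPair,
    min_dist: int = DEFAULT_MIN_DIST,
    max_dist: int = DEFAULT_MAX_DIST,
) -> MappingResult:
    """Place a pair by its two seed 21-mers under the distance rule.

    Candidates pair a forward-strand hit of one seed with a reverse-strand
    hit of the other, facing inward (the forward seed upstream of the
    reverse seed's right end). End-to-end distance is the inclusive span
    from the leftmost to the rightmost seed base; placements outside
    [min_dist, max_dist] are discarded, the minimum-distance survivor wins,
    and a tie at the minimum is reported as ambiguous. ``unmapped`` covers
    both a seed with no exact hit and hit sets admitting no inward-facing
    opposite-strand pairing; ``distance_violation`` means pairings exist but
    all fall outside the distance window.
    """
    k = index.k
    for name, s in (("read 1", pair.seq1), ("read 2", pair.seq2)):
        if len(s) < k:
            raise ValueError(f"{name} of pair {pair.id} is shorter than the {k}-mer seed")
    hits1 = index.query(pair.seq1[:k].upper())
    hits2 = index.query(pair.seq2[:k].upper())
    if not hits1 or not hits2:
        return MappingResult(pair.id, "unmapped")

    spans = []
    for plus_hits, minus_hits in ((hits1, hits2), (hits2, hits1)):
        for p_pos, p_str in plus_hits:
            if p_str != "+":
                continue
            for m_pos, m_str in minus_hits:
                if m_str != "-":
                    continue
                start, end = p_pos, m_pos + k - 1
                if start <= end:
                    spans.append((start, end))
    if not spans:
        return MappingResult(pair.id, "unmapped")

    # a placement is identified by its span; palindromic seeds can reach the
    # same span through both read-role assignments
    spans = sorted(set(spans))
    valid = [(s, e) for s, e in spans if min_dist <= e - s + 1 <= max_dist]
    if not valid:
        return MappingResult(pair.id, "distance_violation")

    best = min(e - s + 1 for s, e in valid)
    winners = [(s, e) for s, e in valid if e - s + 1 == best]
    if len(winners) > 1:
        return MappingResult(pair.id, "ambiguous", n_candidates=len(valid))
    s, e = winners[0]
    return MappingResult(pair.id, "mapped", s, e, best, n_candidates=len(valid))


def map_pairs(index: KmerIndex, pairs, **kw) -> list[MappingResult]:
    return [map_pair(index, p, **kw) for p in pairs]


# ---------------------------------------------------------------------------
# Transcript counting and expression comparison
# ---------------------------------------------------------------------------

@dataclass
class CountTable:
    counts: dict[str, int]
    reference_feature: str | None = None

    def normalized(self) -> dict[str, float]:
        if self.reference_feature is None:
            raise ValueError("no reference feature set")
        ref = self.counts.get(self.reference_feature, 0)
        if ref <= 0:
            raise ValueError(f"reference feature {self.reference_feature!r} has zero count")
        return {g: c / ref for g, c in self.counts.items()}

    def to_frame(self) -> pd.DataFrame:
        rows = [(g, c) for g, c in sorted(self.counts.items())]
        df = pd.DataFrame(rows, columns=["feature", "count"])
        if self.reference_feature is not None and self.counts.get(self.reference_feature, 0) > 0:
            norm = self.normalized()
            df["normalized"] = [norm[g] for g in df["feature"]]
        return df


def count_spans(
    results: list[MappingResult],
    features: list[Feature],
    reference: str | None = None,
) -> CountTable:
    """Count each mapped span against every gene it overlaps by >= 1 bp.

    Ambiguous, unmapped and distance-violating pairs contribute nothing. A
    span overlapping several genes increments each of them.
    """
    genes = [f for f in features if f.kind == "gene"]
    counts = {g.name: 0 for g in genes}
    for r in results:
        if r.status != "mapped":
            continue
        for g in genes:
            if g.overlaps(r.span_start, r.span_end):
                counts[g.name] += 1
    return CountTable(counts=counts, reference_feature=reference)


def fold_change(
    table_a: CountTable, table_b: CountTable, reference: str
) -> dict[str, float]:
    """Reference-normalised expression ratio b/a per gene.

    ``fold(g) = (b_g / b_ref) / (a_g / a_ref)``. Genes with zero count in
    condition a (but nonzero in b) are reported as ``inf`` so they stay
    distinguishable from large finite changes; genes at zero in both are 0/0
    and reported as ``nan``.
    """
    for label, t in (("a", table_a), ("b", table_b)):
        if t.counts.get(reference, 0) <= 0:
            raise ValueError(f"reference {reference!r} has zero count in table {label}")
    a_ref, b_ref = table_a.counts[reference], table_b.counts[reference]
    out = {}
    for g in sorted(set(table_a.counts) | set(table_b.counts)):
        a = table_a.counts.get(g, 0) / a_ref
        b = table_b.counts.get(g, 0) / b_ref
        if a == 0:
            out[g] = inf if b > 0 else float("nan")
        else:
            out[g] = b / a
    return out


# ---------------------------------------------------------------------------
# Tabular IO
# ---------------------------------------------------------------------------

def results_to_frame(results: list[MappingResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (r.pair_id, r.status, r.span_start, r.span_end, r.distance, r.n_candidates)
            for r in results
        ],
        columns=["pair_id", "status", "span_start", "span_end", "distance", "n_candidates"],
    )


def read_fastq_pairs(path_r1, path_r2) -> list[ReadPair]:
    """Load paired FASTQ files in matched order (\\_R1/\\_R2 convention)."""
    from Bio import SeqIO

    r1 = list(SeqIO.parse(str(path_r1), "fastq"))
    r2 = list(SeqIO.parse(str(path_r2), "fastq"))
    if len(r1) != len(r2):
        raise ValueError(f"unpaired FASTQ files: {len(r1)} vs {len(r2)} records")
    out = []
    for a, b in zip(r1, r2):
        pid = a.id.rsplit("/", 1)[0]
        out.append(ReadPair(pid, str(a.seq).upper(), str(b.seq).upper()))
    return out
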