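"""Shared domain types and sequence/feature IO.

Coordinates are 1-based inclusive throughout, matching GenBank convention.
Sequences are plain uppercase strings over {A, C, G, T, N}.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

FEATURE_KINDS = frozenset(
    {"gene", "attL", "attR", "attP", "attB", "motif", "primer", "REPT", "oriT_core"}
)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe)."""
    return seq.translate(_COMPLEMENT)[::-1]


def hamming(a: str, b: str) -> int:
    """Hamming distance between equal-length strings."""
    if len(a) != len(b):
        raise ValueError(f"unequal lengths: {len(a)} vs {len(b)}")
    return sum(x != y for x, y in zip(a, b))


@dataclass(frozen=True)
class Feature:
    """A strand-aware interval on a genome, 1-based inclusive."""

    name: str
    start: int
    end: int
    strand: str = "+"
    kind: str = "gene"

    def __post_init__(self):
        if not (1 <= self.start <= self.end):
            raise ValueError(f"bad interval for {self.name}: [{self.start}, {self.end}]")
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r}")
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, start: int, end: int) -> bool:
        """True when this feature shares >= 1 bp with [start, end]."""
        return self.start <= end and start <= self.end

    def shifted(self, offset: int) -> "Feature":
        return replace(self, start=self.start + offset, end=self.end + offset)


@dataclass
class GenomeRecord:
    """A named DNA sequence with interval features.

    ``circular`` marks plasmid-like molecules (e.g. the excised attP circle);
    such sequences are stored linearly with a documented rotation (the attP
    junction at position 1) and scanned across the origin where relevant.
    """

    id: str
    seq: str
    features: list[Feature] = field(default_factory=list)
    circular: bool = False

    def __post_init__(self):
        self.seq = self.seq.upper()
        bad = set(self.seq) - set("ACGTN")
        if bad:
            raise ValueError(f"non-DNA characters in {self.id}: {sorted(bad)}")
        for f in self.features:
            if f.end > len(self.seq):
                raise ValueError(
                    f"feature {f.name} [{f.start},{f.end}] exceeds sequence "
                    f"length {len(self.seq)}"
                )

    def __len__(self) -> int:
        return len(self.seq)

    def subseq(self, start: int, end: int) -> str:
        """1-based inclusive slice; wraps around the origin on circular records."""
        if start < 1:
            raise ValueError("start < 1")
        if end <= len(self.seq):
            return self.seq[start - 1 : end]
        if not self.circular:
            raise ValueError(f"[{start},{end}] exceeds linear sequence of {len(self)}")
        return (self.seq + self.seq)[start - 1 : end]

    def feature_seq(self, feat: Feature) -> str:
        s = self.subseq(feat.start, feat.end)
        return revcomp(s) if feat.strand == "-" else s

    def get_features(self, kind: str | None = None, name: str | None = None) -> list[Feature]:
        out = self.features
        if kind is not None:
            out = [f for f in out if f.kind == kind]
        if name is not None:
            out = [f for f in out if f.name == name]
        return out

    def require_feature(self, name: str) -> Feature:
        hits = self.get_features(name=name)
        if not hits:
            raise KeyError(f"genome {self.id} has no feature named {name!r}")
        return hits[0]


# ---------------------------------------------------------------------------
# IO: FASTA / FASTQ / feature tables
# ---------------------------------------------------------------------------

def write_fasta(records: list[GenomeRecord] | GenomeRecord, path) -> None:
    """Write genomes as 60-column-wrapped FASTA."""
    if isinstance(records, GenomeRecord):
        records = [records]
    seqs = [SeqRecord(Seq(r.seq), id=r.id, description="") for r in records]
    SeqIO.write(seqs, str(path), "fasta")


def read_fasta(path) -> list[GenomeRecord]:
    return [GenomeRecord(id=rec.id, seq=str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def write_feature_table(record: GenomeRecord, path) -> None:
    """1-based inclusive TSV: name, start, end, strand, kind."""
    df = pd.DataFrame(
        [(f.name, f.start, f.end, f.strand, f.kind) for f in record.features],
        columns=["name", "start", "end", "strand", "kind"],
    )
    df.to_csv(path, sep="\t", index=False)


def read_feature_table(path) -> list[Feature]:
    df = pd.read_csv(path, sep="\t")
    return [
        Feature(row["name"], int(row["start"]), int(row["end"]), row["strand"], row["kind"])
        for _, row in df.iterrows()
    ]
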