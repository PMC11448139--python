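"""LysR binding-site and sigma-70 promoter scanning.

LysR-family transcriptional regulators bind a T-N11-A motif: a conserved T
and a conserved A exactly 13 positions apart (11 spacer nucleotides), with
the T and A forming the innermost bases of a short, possibly interrupted
inverted repeat. The scanners here detect full T-N11-A sites with a
mismatch-tolerant arm comparison, mismatch-tolerant similarity matches to a
known site, and isolated half-sites (one arm of the dyad, e.g. CAAAACG),
plus sigma-70 -35/-10 promoter boxes by an additive homology score, and the
site-to-promoter architecture ("immediately upstream of the -35 box") that
distinguishes a plausibly regulated promoter.

Known binding-site sequences of the ICE_KKS102_Tn4677 system are packaged
as constants (BINDING_SITES): the full sites upstream of xis and of the
C380_15836 gene, and the half-sites near traG, traR and within the oriT
conserved 20-mer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import hamming, revcomp

#: Published TraR-associated binding-site sequences of ICE_KKS102_Tn4677.
BINDING_SITES = {
    "BSxis": "CGTTTTGATGGAGACGCAAAACG",    # full T-N11-A site upstream of xis
    "BS15836": "TTTATTGAATCATTGGCAAAACG",  # similar site upstream of C380_15836
    "BStraG": "CAAAACG",                   # half-site upstream of traG promoter
    "BSoriT": "CAAAAGG",                   # half-site inside the oriT conserved 20-mer
    "BStraR": "CAAAA",                     # less-conserved half-site at the traR promoter
}

TN11A_SPACER = 11  # nucleotides between the conserved T and A


@dataclass(frozen=True)
class MotifHit:
    seq_id: str
    t_pos: int  # 1-based position of the conserved T (forward coordinates)
    a_pos: int  # 1-based position of the conserved A; a_pos - t_pos = 12
    arm_len: int
    arm_mismatches: int
    strand: str
    site_seq: str

    @property
    def spacer_len(self) -> int:
        return self.a_pos - self.t_pos - 1

    @property
    def start(self) -> int:
        return self.t_pos - self.arm_len + 1

    @property
    def end(self) -> int:
        return self.a_pos + self.arm_len - 1


@dataclass(frozen=True)
class HalfSiteHit:
    seq_id: str
    start: int
    strand: str
    consensus_used: str
    mismatches: int

    @property
    def end(self) -> int:
        return self.start + len(self.consensus_used) - 1


def _tn11a_forward(seq: str, seq_id: str, arm_len: int, max_mm: int, strand: str):
    """Hits of T-N11-A with complementary arms on one strand of seq.

    The arm includes the conserved base itself: left arm = arm_len bases
    ending at the T, right arm = arm_len bases starting at the A.
    """
    hits = []
    L = len(seq)
    for i in range(arm_len - 1, L - TN11A_SPACER - arm_len):
        if seq[i] != "T" or seq[i + TN11A_SPACER + 1] != "A":
            continue
        left = seq[i - arm_len + 1 : i + 1]
        right = seq[i + TN11A_SPACER + 1 : i + TN11A_SPACER + 1 + arm_len]
        mm = hamming(left, revcomp(right))
        if mm <= max_mm:
            hits.append((i + 1, mm, seq[i - arm_len + 1 : i + TN11A_SPACER + 1 + arm_len]))
    out = []
    for t_pos, mm, site in hits:
        out.append(
            MotifHit(seq_id, t_pos, t_pos + TN11A_SPACER + 1, arm_len, mm, strand, site)
        )
    return out


def find_tn11a(
    seq: str,
    arm_len: int = 5,
    max_arm_mismatch: int = 1,
    both_strands: bool = True,
    seq_id: str = "seq",
) -> list[MotifHit]:
    """Scan for the LysR T-N11-A motif inside an interrupted inverted repeat.

    Positions are 1-based forward coordinates on either strand. The motif is
    its own reverse complement (T-N11-A reads as T-N11-A on the other strand
    with the arms swapped), so every reverse-strand hit coincides with a
    forward hit at the same location; duplicates are collapsed keeping the
    forward call.
    """
    if arm_len < 1:
        raise ValueError("arm_len must be >= 1")
    seq = seq.upper()
    hits = _tn11a_forward(seq, seq_id, arm_len, max_arm_mismatch, "+")
    if both_strands:
        L = len(seq)
        for h in _tn11a_forward(revcomp(seq), seq_id, arm_len, max_arm_mismatch, "-"):
            t_fwd = L - h.a_pos + 1  # minus-strand A sits under a forward T
            a_fwd = L - h.t_pos + 1
            mirrored = MotifHit(
                seq_id, t_fwd, a_fwd, arm_len, h.arm_mismatches, "-", revcomp(h.site_seq)
            )
            if not any(x.t_pos == t_fwd and x.a_pos == a_fwd for x in hits):
                hits.append(mirrored)
    return sorted(hits, key=lambda h: (h.t_pos, h.strand))


@dataclass(frozen=True)
class SimilarityHit:
    q_offset: int  # 1-based offset in the query
    s_offset: int  # 1-based offset in the subject (forward coordinates)
    strand: str
    mismatches: int


def similarity_search(
    query: str, subject: str, window: int, max_mismatch: int
) -> list[SimilarityHit]:
    """All Hamming alignments of query windows against subject windows.

    Substitution-only comparison (no indels), both subject strands, sorted
    by mismatch count then subject position. A reverse-strand hit's offset is
    the forward-strand start of the matched subject window.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    query, subject = query.upper(), subject.upper()
    if window > min(len(query), len(subject)):
        raise ValueError("window exceeds a sequence length")
    hits = []
    for strand, subj in (("+", subject), ("-", revcomp(subject))):
        for qi in range(len(query) - window + 1):
            qw = query[qi : qi + window]
            for si in range(len(subj) - window + 1):
                mm = hamming(qw, subj[si : si + window])
                if mm <= max_mismatch:
                    s_off = si + 1 if strand == "+" else len(subject) - (si + window) + 1
                    hits.append(SimilarityHit(qi + 1, s_off, strand, mm))
    return sorted(hits, key=lambda h: (h.mismatches, h.s_offset, h.q_offset, h.strand))


def find_half_sites(
    seq: str,
    consensus: str = BINDING_SITES["BStraG"],
    max_mismatch: int = 1,
    seq_id: str = "seq",
) -> list[HalfSiteHit]:
    """Mismatch-tolerant occurrences of one dyad half-site on both strands."""
    seq, consensus = seq.upper(), consensus.upper()
    if set(consensus) - set("ACGT"):
        raise ValueError("consensus must be over {A,C,G,T}")
    w = len(consensus)
    hits = []
    rc = revcomp(consensus)
    for i in range(len(seq) - w + 1):
        win = seq[i : i + w]
        mm = hamming(win, consensus)
        if mm <= max_mismatch:
            hits.append(HalfSiteHit(seq_id, i + 1, "+", consensus, mm))
        mm_rc = hamming(win, rc)
        if mm_rc <= max_mismatch:
            hits.append(HalfSiteHit(seq_id, i + 1, "-", consensus, mm_rc))
    return hits


# ---------------------------------------------------------------------------
# Sigma-70 promoter prediction
# ---------------------------------------------------------------------------

# Additive homology weight table for the -35 (TTGACA) and -10 (TATAAT)
# hexamers, derived from compiled E. coli sigma-70 promoter alignments: each
# position scores the consensus base by its conservation percentage and the
# three alternatives uniformly with the remainder. Versioned constant; the
# calls depend on score ordering, not on the absolute numbers.
SIGMA70_TABLE_VERSION = "ec-sigma70-1"
_M35_CONS = ("TTGACA", (82, 84, 79, 64, 54, 45))
_M10_CONS = ("TATAAT", (79, 95, 44, 59, 51, 96))


def _weight_matrix(consensus: str, conservation) -> dict[str, np.ndarray]:
    mat = {b: np.zeros(len(consensus)) for b in "ACGT"}
    for i, (cb, c) in enumerate(zip(consensus, conservation)):
        for b in "ACGT":
            mat[b][i] = c if b == cb else (100.0 - c) / 3.0
    return mat


_M35 = _weight_matrix(*_M35_CONS)
_M10 = _weight_matrix(*_M10_CONS)
_M35_MAX = sum(_M35_CONS[1])
_M10_MAX = sum(_M10_CONS[1])

SPACER_RANGE = (15, 21)
SPACER_OPTIMUM = 17
SPACER_PENALTY = 0.02  # score units per bp away from the 17-bp optimum


def _hexamer_score(hexamer: str, mat) -> float:
    try:
        return float(sum(mat[b][i] for i, b in enumerate(hexamer)))
    except KeyError:  # N or other ambiguity: no contribution
        return 0.0


@dataclass(frozen=True)
class PromoterCall:
    seq_id: str
    minus35_start: int
    minus35_seq: str
    minus10_start: int
    minus10_seq: str
    score: float

    @property
    def spacer_len(self) -> int:
        return self.minus10_start - (self.minus35_start + 6)


def predict_promoters(
    seq: str, min_score: float = 0.8, seq_id: str = "seq"
) -> list[PromoterCall]:
    """Score every -35/-10 hexamer pair with a 15-21 bp spacer.

    The score is the mean of the two normalised hexamer homology scores
    (consensus = 1.0) minus a linear penalty per bp of deviation from the
    17-bp optimal spacer. Calls scoring >= ``min_score`` are returned sorted
    by decreasing score. Scans the given strand only; run on the reverse
    complement for divergent promoters.
    """
    seq = seq.upper()
    lo, hi = SPACER_RANGE
    calls = []
    for i in range(len(seq) - (12 + lo) + 1):
        h35 = seq[i : i + 6]
        s35 = _hexamer_score(h35, _M35) / _M35_MAX
        for spacer in range(lo, hi + 1):
            j = i + 6 + spacer
            if j + 6 > len(seq):
                break
            h10 = seq[j : j + 6]
            s10 = _hexamer_score(h10, _M10) / _M10_MAX
            score = 0.5 * (s35 + s10) - SPACER_PENALTY * abs(spacer - SPACER_OPTIMUM)
            if score >= min_score:
                calls.append(PromoterCall(seq_id, i + 1, h35, j + 1, h10, round(score, 6)))
    return sorted(calls, key=lambda c: (-c.score, c.minus35_start))


@dataclass(frozen=True)
class SitePromoterPair:
    site: object  # MotifHit or HalfSiteHit
    promoter: PromoterCall
    gap: int  # bases between site end and -35 start
    immediately_upstream: bool


def site_promoter_architecture(
    motifs, promoters: list[PromoterCall], max_gap: int = 5
) -> list[SitePromoterPair]:
    """Pair each site with its nearest downstream promoter.

    A site whose end lies within ``max_gap`` bases of the -35 box start is
    flagged ``immediately_upstream`` — the architecture of a canonical
    LysR-regulated promoter. Sites with no downstream promoter are omitted.
    """
    out = []
    for site in motifs:
        downstream = [p for p in promoters if p.minus35_start > site.end]
        if not downstream:
            continue
        nearest = min(downstream, key=lambda p: p.minus35_start - site.end)
        gap = nearest.minus35_start - site.end - 1
        out.append(SitePromoterPair(site, nearest, gap, gap <= max_gap))
    return out
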