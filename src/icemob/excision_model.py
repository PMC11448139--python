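"""att-site recombination model for ICE excision and integration.

An integrated ICE is flanked by two identical direct repeats (attL and attR;
9 bp GATTTTAAG for ICE_KKS102_Tn4677). Excisionase-stimulated site-specific
recombination between attL and attR releases a circular molecule carrying one
repeat copy at its attP junction and leaves the other copy at attB on the
chromosome. This module detects the boundary repeat, performs the excision /
integration sequence arithmetic with full feature bookkeeping, predicts which
qPCR primer sets amplify which template (the circular form, the vacated attB
site, or both forms), and computes internal-standard-normalised relative
quantification of excision over a time course.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import pandas as pd

from .core import Feature, GenomeRecord, revcomp

MIN_REPEAT_LEN = 6  # below this, chance direct-repeat matches dominate


@dataclass
class ExcisionProducts:
    """The two molecules produced by attL x attR recombination."""

    circle: GenomeRecord  # attP-bearing circular molecule
    chromosome: GenomeRecord  # attB-bearing chromosome
    repeat_seq: str

    @property
    def repeat_len(self) -> int:
        return len(self.repeat_seq)


@dataclass(frozen=True)
class PrimerPair:
    name: str
    fwd: str
    rev: str
    max_product: int = 2000

    def __post_init__(self):
        for p in (self.fwd, self.rev):
            if len(p) < 15:
                raise ValueError(f"primer shorter than 15 nt in set {self.name}")


@dataclass
class QpcrPanel:
    """Internal-standard-normalised relative copy numbers per timepoint.

    ``normalized``: target -> {timepoint -> raw/normalizer}; ``fold_change``:
    target -> {timepoint -> normalized/normalized-at-first-timepoint}, so the
    first timepoint is 1 for every target.
    """

    normalizer: str
    timepoints: list
    normalized: dict
    fold_change: dict

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for target in self.normalized:
            for t in self.timepoints:
                rows.append(
                    (target, t, self.normalized[target][t], self.fold_change[target][t])
                )
        return pd.DataFrame(rows, columns=["target", "timepoint", "normalized", "fold_change"])


# ---------------------------------------------------------------------------
# Boundary repeat detection
# ---------------------------------------------------------------------------

def _longest_shared_kmer(left: str, right: str, min_len: int):
    """Longest substring occurring in both windows (binary search over k).

    Returns (kmer, left_offset, right_offset) with 0-based offsets, or None.
    """
    lo, hi = min_len, min(len(left), len(right))
    best = None
    while lo <= hi:
        k = (lo + hi) // 2
        kmers = {}
        for i in range(len(left) - k + 1):
            kmers.setdefault(left[i : i + k], i)
        found = None
        for j in range(len(right) - k + 1):
            w = right[j : j + k]
            if w in kmers:
                found = (w, kmers[w], j)
                break
        if found:
            best = found
            lo = k + 1
        else:
            hi = k - 1
    return best


def detect_boundary_repeat(
    chromosome: GenomeRecord,
    element_hint: tuple[int, int] | None = None,
    min_len: int = MIN_REPEAT_LEN,
    flank_margin: int = 500,
):
    """Find the maximal direct repeat pair flanking an integrated element.

    Returns ``(repeat_seq, (attL_start, attL_end), (attR_start, attR_end))``
    in 1-based coordinates. The returned pair is maximal: extending either
    copy by one base on either side breaks identity. With ``element_hint``
    (approximate 1-based element interval) only the hint's flanks are
    searched, which keeps the scan linear on long chromosomes.
    """
    seq = chromosome.seq
    if element_hint is None:
        hit = _longest_repeated_pair(seq, min_len)
        if hit is None:
            raise ValueError(f"no direct repeat pair of length >= {min_len} found")
        repeat, i, j = hit
    else:
        hs, he = element_hint
        l_lo = max(0, hs - 1 - flank_margin)
        l_hi = min(len(seq), hs - 1 + flank_margin)
        r_lo = max(0, he - flank_margin)
        r_hi = min(len(seq), he + flank_margin)
        found = _longest_shared_kmer(seq[l_lo:l_hi], seq[r_lo:r_hi], min_len)
        if found is None:
            raise ValueError(f"no direct repeat pair of length >= {min_len} found in flanks")
        repeat, li, rj = found
        i, j = l_lo + li, r_lo + rj
        if j <= i:
            raise ValueError("flanking repeat copies are not ordered left-right")
    k = len(repeat)
    return repeat, (i + 1, i + k), (j + 1, j + k)


def _longest_repeated_pair(seq: str, min_len: int):
    """Longest substring with >= 2 non-identical occurrences (binary search)."""
    lo, hi = min_len, len(seq) // 2
    best = None
    while lo <= hi:
        k = (lo + hi) // 2
        seen = {}
        found = None
        for i in range(len(seq) - k + 1):
            w = seq[i : i + k]
            if w in seen:
                found = (w, seen[w], i)
                break
            seen[w] = i
        if found:
            best = found
            lo = k + 1
        else:
            hi = k - 1
    return best


# ---------------------------------------------------------------------------
# Excision / integration arithmetic
# ---------------------------------------------------------------------------

def excise(
    chromosome: GenomeRecord,
    attL: tuple[int, int],
    attR: tuple[int, int],
) -> ExcisionProducts:
    """Recombine attL with attR, releasing the circular form.

    The crossover is placed at the repeat's left edge, so the circle keeps
    the attL repeat copy (at its attP junction, rotated to position 1) and
    the chromosome keeps the attR copy at attB. Because the two copies are
    identical the products do not depend on this convention.

    Conserves total length: ``len(circle) + len(chromosome)`` equals the
    input length. Features wholly inside the element move to the circle;
    flank features stay on the chromosome (downstream ones shifted); features
    straddling a crossover are dropped.
    """
    s1, e1 = attL
    s2, e2 = attR
    if not (s1 <= e1 < s2 <= e2):
        raise ValueError("attL must lie entirely left of attR")
    seq = chromosome.seq
    rep_l = seq[s1 - 1 : e1]
    rep_r = seq[s2 - 1 : e2]
    if rep_l != rep_r:
        raise ValueError(
            f"att sequences differ ({rep_l} vs {rep_r}): not a valid recombination substrate"
        )
    rep = rep_l
    rlen = len(rep)

    circle_seq = seq[s1 - 1 : s2 - 1]  # attL copy .. element payload
    chrom_seq = seq[: s1 - 1] + rep + seq[e2:]

    circ_feats = [Feature("attP", 1, rlen, "+", "attP")]
    chrom_feats = [Feature("attB", s1, s1 + rlen - 1, "+", "attB")]
    shift_down = -(s2 - s1)  # removal of element payload + one repeat copy
    for f in chromosome.features:
        if f.kind in ("attL", "attR"):
            continue
        if f.start >= s1 and f.end <= s2 - 1:  # inside the circle slice
            circ_feats.append(f.shifted(-(s1 - 1)))
        elif f.end <= s1 - 1:
            chrom_feats.append(f)
        elif f.start >= e2 + 1:
            chrom_feats.append(f.shifted(shift_down))
        # else: straddles a junction -> dropped

    circle = GenomeRecord(
        id=f"{chromosome.id}_attP_circle", seq=circle_seq, features=circ_feats, circular=True
    )
    chrom = GenomeRecord(
        id=f"{chromosome.id}_attB_chromosome", seq=chrom_seq, features=chrom_feats
    )
    assert len(circle) + len(chrom) == len(chromosome)
    return ExcisionProducts(circle=circle, chromosome=chrom, repeat_seq=rep)


def integrate(
    circle: GenomeRecord,
    chromosome: GenomeRecord,
    attB: tuple[int, int],
    out_id: str | None = None,
) -> GenomeRecord:
    """Insert the circular form at attB — the inverse of :func:`excise`.

    The circle must be in attP-junction-first rotation (one repeat copy at
    position 1, as produced by ``excise``) and its junction repeat must equal
    the chromosome's attB repeat.
    """
    s, e = attB
    rlen = e - s + 1
    rep_chrom = chromosome.seq[s - 1 : e]
    rep_circ = circle.seq[:rlen]
    if rep_chrom != rep_circ:
        raise ValueError(
            f"attP repeat {rep_circ} does not match attB repeat {rep_chrom}"
        )
    seq = chromosome.seq[: s - 1] + circle.seq + chromosome.seq[s - 1 :]
    clen = len(circle)
    feats = [
        Feature("attL", s, s + rlen - 1, "+", "attL"),
        Feature("attR", s + clen, s + clen + rlen - 1, "+", "attR"),
    ]
    for f in circle.features:
        if f.kind == "attP":
            continue
        feats.append(f.shifted(s - 1))
    for f in chromosome.features:
        if f.kind == "attB":
            continue
        if f.end <= s - 1:
            feats.append(f)
        elif f.start >= s:
            feats.append(f.shifted(clen))
    return GenomeRecord(
        id=out_id or f"{chromosome.id}_integrated", seq=seq, features=feats
    )


# ---------------------------------------------------------------------------
# qPCR amplicon prediction and relative quantification
# ---------------------------------------------------------------------------

def _find_all(text: str, sub: str) -> list[int]:
    """All 0-based occurrence starts of sub in text."""
    out, i = [], text.find(sub)
    while i != -1:
        out.append(i)
        i = text.find(sub, i + 1)
    return out


def _amplicons_one_orientation(seq: str, fwd: str, rev: str, max_product: int) -> list[int]:
    """Product lengths for fwd annealing the top strand, rev the bottom."""
    lens = []
    rev_site = revcomp(rev)
    for i in _find_all(seq, fwd):
        for j in _find_all(seq, rev_site):
            end = j + len(rev_site) - 1
            product = end - i + 1
            if len(fwd) <= product <= max_product:
                lens.append(product)
    return lens


def predict_amplicons(
    templates: list[GenomeRecord], primers: list[PrimerPair]
) -> pd.DataFrame:
    """Exact-match PCR product table: template x primer set.

    A product runs from the forward primer's 5' end to the reverse primer's
    5' end, both primers matching exactly, facing inward, product length
    <= max_product. Both template orientations are checked. Circular templates
    are scanned across the origin. Cell values: product length (bp), ``None``
    (no product), or the string ``"nonspecific"`` when one primer set yields
    multiple products on a template.
    """
    rows = {}
    for tpl in templates:
        seq = tpl.seq + (tpl.seq[: max(p.max_product for p in primers)] if tpl.circular else "")
        row = {}
        for p in primers:
            lens = _amplicons_one_orientation(seq, p.fwd, p.rev, p.max_product)
            lens += _amplicons_one_orientation(seq, p.rev, p.fwd, p.max_product)
            if tpl.circular:
                # a site counted twice through the origin extension is one site
                lens = sorted(set(lens))
            if not lens:
                row[p.name] = None
            elif len(lens) > 1:
                row[p.name] = "nonspecific"
            else:
                row[p.name] = lens[0]
        rows[tpl.id] = row
    return pd.DataFrame.from_dict(rows, orient="index")


def make_qpcr_primer_sets(
    integrated: GenomeRecord,
    attL: tuple[int, int],
    attR: tuple[int, int],
    primer_len: int = 20,
    max_product: int = 300,
) -> list[PrimerPair]:
    """Design the three diagnostic primer sets from an integrated genome.

    * ``set_a`` detects the circular form only: both primers sit inside the
      element pointing outward across attL/attR, so they converge only across
      the attP junction of the circle.
    * ``set_b`` detects the vacated attB site only: primers in the host flanks
      pointing inward; on the integrated form the element separates them
      beyond max_product.
    * ``set_c`` detects both integrated and excised element forms: both
      primers internal to the element (the internal standard).
    """
    s1, e1 = attL
    s2, e2 = attR
    seq = integrated.seq
    gap = 40  # distance from each junction to the primer
    # set_a: fwd near element right end (top strand, pointing toward attR);
    # rev near element left end (its revcomp on top strand just inside attL)
    a_fwd = seq[s2 - 1 - gap - primer_len : s2 - 1 - gap]
    a_rev = revcomp(seq[e1 + gap : e1 + gap + primer_len])
    # set_b: host flank primers converging across the att site
    b_fwd = seq[s1 - 1 - gap - primer_len : s1 - 1 - gap]
    b_rev = revcomp(seq[e2 + gap : e2 + gap + primer_len])
    # set_c: internal to the element payload
    mid = (e1 + s2) // 2
    c_fwd = seq[mid : mid + primer_len]
    c_rev = revcomp(seq[mid + 60 : mid + 60 + primer_len])
    return [
        PrimerPair("set_a", a_fwd, a_rev, max_product),
        PrimerPair("set_b", b_fwd, b_rev, max_product),
        PrimerPair("set_c", c_fwd, c_rev, max_product),
    ]


def quantify_excision(panel_raw: pd.DataFrame, normalizer: str = "set_c") -> QpcrPanel:
    """Relative quantification with an internal standard.

    ``panel_raw``: long-form DataFrame with columns target, timepoint, value
    (measured copies). Each target is divided by the normalizer at the same
    timepoint (correcting for template DNA amount), then expressed relative
    to the first timepoint, which is set to 1.
    """
    req = {"target", "timepoint", "value"}
    if not req.issubset(panel_raw.columns):
        raise ValueError(f"panel must have columns {sorted(req)}")
    wide = panel_raw.pivot_table(index="timepoint", columns="target", values="value")
    if normalizer not in wide.columns:
        raise ValueError(f"normalizer {normalizer!r} not present in panel")
    if (wide[normalizer] <= 0).any():
        raise ValueError("normalizer values must be positive at every timepoint")
    timepoints = sorted(wide.index)
    t0 = timepoints[0]
    normalized, fold = {}, {}
    for target in wide.columns:
        norm = wide[target] / wide[normalizer]
        if norm.loc[t0] == 0:
            raise ValueError(f"target {target!r} is zero at the first timepoint; fold undefined")
        normalized[target] = {t: float(norm.loc[t]) for t in timepoints}
        fold[target] = {t: float(norm.loc[t] / norm.loc[t0]) for t in timepoints}
    return QpcrPanel(
        normalizer=normalizer, timepoints=timepoints, normalized=normalized, fold_change=fold
    )
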