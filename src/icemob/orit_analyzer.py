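"""Dissection of the oriT (origin-of-transfer) region.

The oriT of a conjugative element is the cis-acting region nicked by the
relaxase to initiate transfer. For ICE_KKS102_Tn4677 it lies in the
traF-traI intergenic region (463 bp) and its functional anatomy was mapped
by a deletion series: a conserved 20-bp sequence plus the adjacent inverted
repeat REPT1 are essential (positions 261-318, 58 bp), the region around
REPT2 enhances transfer by about two orders of magnitude, and REPT3 and two
LysR motifs are dispensable. This module finds inverted repeats with a
mismatch budget, locates the most conserved fixed-length window across
homologous regions, classifies deletion constructs by the features they
retain, intersects the functional constructs into the minimal essential
region, and re-evaluates inverted-repeat integrity after base substitutions
(mutated arms may still pair, e.g. with one mismatch in eight).
"""

from __future__ import annotations

from dataclasses import dataclass
from warnings import warn

import numpy as np
import pandas as pd

from .core import hamming, revcomp


@dataclass(frozen=True)
class InvertedRepeat:
    left_start: int
    left_end: int
    right_start: int
    right_end: int
    mismatches: int
    label: str = ""

    @property
    def arm_len(self) -> int:
        return self.left_end - self.left_start + 1

    @property
    def loop_len(self) -> int:
        return self.right_start - self.left_end - 1

    def arms(self, seq: str) -> tuple[str, str]:
        return (
            seq[self.left_start - 1 : self.left_end],
            seq[self.right_start - 1 : self.right_end],
        )


def find_inverted_repeats(
    seq: str, min_arm: int = 4, max_loop: int = 12, max_mismatch: int = 0
) -> list[InvertedRepeat]:
    """All maximal inverted-repeat arm pairs within the constraints.

    For every candidate loop placement the arms are extended outward while
    the mismatch budget allows, then trimmed so both outermost arm bases
    pair (a maximal arm never ends on a mismatch). Hits wholly contained in
    a longer hit with no more mismatches are suppressed.
    """
    if min_arm < 3:
        raise ValueError("min_arm must be >= 3")
    seq = seq.upper()
    L = len(seq)
    pair = {"A": "T", "T": "A", "C": "G", "G": "C"}
    raw = []
    for l_end in range(L):  # 0-based index of left arm's innermost base
        for loop in range(0, max_loop + 1):
            r_start = l_end + 1 + loop
            if r_start >= L:
                break
            # extend outward, tracking mismatch positions to trim the ends
            mism: list[int] = []
            a = 0
            states = []  # (arm_len, n_mismatches) after each extension
            while l_end - a >= 0 and r_start + a < L:
                match = pair.get(seq[l_end - a]) == seq[r_start + a]
                if not match:
                    mism.append(a)
                if len(mism) > max_mismatch:
                    break
                a += 1
                states.append((a, len(mism)))
            # trim so the outermost pair matches
            while states and states[-1][0] - 1 in mism:
                states.pop()
            if not states:
                continue
            arm, mm = states[-1]
            if arm < min_arm:
                continue
            raw.append(
                InvertedRepeat(
                    left_start=l_end - arm + 2,
                    left_end=l_end + 1,
                    right_start=r_start + 1,
                    right_end=r_start + arm,
                    mismatches=mm,
                )
            )
    return _suppress_contained(raw)


def _suppress_contained(hits: list[InvertedRepeat]) -> list[InvertedRepeat]:
    hits = sorted(set(hits), key=lambda h: (h.left_start, -h.arm_len, h.right_end))
    kept: list[InvertedRepeat] = []
    for h in hits:
        contained = any(
            k.left_start <= h.left_start
            and h.left_end <= k.left_end
            and k.right_start <= h.right_start
            and h.right_end <= k.right_end
            and k.mismatches <= h.mismatches
            and (k.arm_len > h.arm_len or (k.arm_len == h.arm_len and k != h))
            for k in kept
        )
        if not contained:
            kept.append(h)
    return kept


# ---------------------------------------------------------------------------
# Conserved-window discovery
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConservedWindow:
    start: int  # 1-based on the reference
    length: int
    mean_identity: float
    per_homolog: tuple[float, ...]

    @property
    def end(self) -> int:
        return self.start + self.length - 1


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8)


def _window_matrix(arr: np.ndarray, w: int) -> np.ndarray:
    return np.lib.stride_tricks.sliding_window_view(arr, w)


def find_conserved_window(
    reference: str, homologs: list[str], window: int = 20
) -> ConservedWindow:
    """Best-conserved fixed-length window of the reference across homologs.

    For each reference window, each homolog contributes its best Hamming
    identity over all same-length windows on either strand (an alignment-free
    stand-in for a column of a multiple alignment). The window with maximal
    mean identity wins; ties go to the leftmost. Homologs shorter than the
    window are rejected rather than scored on partial overlap.
    """
    reference = reference.upper()
    if not homologs:
        raise ValueError("at least one homolog is required")
    if window > len(reference):
        raise ValueError("window exceeds reference length")
    for i, h in enumerate(homologs):
        if len(h) < window:
            raise ValueError(f"homolog {i} shorter than the {window}-bp window")

    ref_wins = _window_matrix(_encode(reference), window)  # (n_ref, w)
    hom_wins = []
    for h in homologs:
        h = h.upper()
        fwd = _window_matrix(_encode(h), window)
        rev = _window_matrix(_encode(revcomp(h)), window)
        hom_wins.append(np.vstack([fwd, rev]))

    n_ref = ref_wins.shape[0]
    scores = np.zeros((n_ref, len(homologs)))
    for j, hw in enumerate(hom_wins):
        for i in range(n_ref):
            matches = (hw == ref_wins[i]).sum(axis=1)
            scores[i, j] = matches.max() / window
    mean = scores.mean(axis=1)
    best = int(np.argmax(mean))  # argmax returns the leftmost maximum
    return ConservedWindow(
        start=best + 1,
        length=window,
        mean_identity=float(mean[best]),
        per_homolog=tuple(float(x) for x in scores[best]),
    )


# ---------------------------------------------------------------------------
# Deletion-series classification
# ---------------------------------------------------------------------------

#: Feature coordinates of the traF-traI intergenic (oriT) region used by the
#: packaged deletion-series fixture. The published figure is not machine
#: readable, so these are synthetic stand-in coordinates consistent with the
#: reported deletion endpoints (functional through 261 from the left, lost at
#: 298; functional through 393 from the right; minimal construct 261-318).
ORIT_FEATURES = {
    "LysR-motif-1": (120, 143),
    "LysR-motif-2": (170, 193),
    "conserved20": (266, 285),
    "REPT1": (293, 318),
    "REPT2": (335, 365),
    "REPT3": (400, 430),
}

#: The deletion series of the 463-bp oriT region: construct name ->
#: (retained intervals, transfer detectable?). Left deletions trim from the
#: traF side, right deletions from the traI side.
ORIT_DELETION_SERIES = {
    "pICEoriT": ([(1, 463)], True),
    "del4": ([(261, 463)], True),   # both LysR motifs removed
    "del8": ([(298, 463)], False),  # conserved 20-mer disrupted
    "del6": ([(1, 393)], True),
    "del7": ([(1, 330)], True),     # REPT2 lost: ~100-fold lower but detectable
    "del9": ([(1, 318)], True),     # trimmed to just after REPT1
    "del17": ([(1, 310)], False),   # REPT1 disrupted
    "del25": ([(261, 318)], True),  # minimal functional construct
}


@dataclass(frozen=True)
class ConstructCall:
    name: str
    retained: tuple[tuple[int, int], ...]
    retains: dict
    predicted_class: str  # functional | attenuated | nonfunctional

    @property
    def transfer_detectable(self) -> bool:
        return self.predicted_class in ("functional", "attenuated")

    def __hash__(self):
        return hash((self.name, self.retained, self.predicted_class))


@dataclass(frozen=True)
class EssentialRegion:
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def _interval_subset(feat: tuple[int, int], retained) -> bool:
    """Is the feature interval fully inside the union of retained intervals?

    Retained intervals are merged first, so a feature spanning two abutting
    kept pieces still counts as retained.
    """
    merged = []
    for s, e in sorted(retained):
        if merged and s <= merged[-1][1] + 1:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    fs, fe = feat
    return any(s <= fs and fe <= e for s, e in merged)


def classify_constructs(
    constructs: dict | list,
    features: dict[str, tuple[int, int]] | None = None,
    required: tuple[str, str] = ("conserved20", "REPT1"),
    enhancer: str = "REPT2",
) -> list[ConstructCall]:
    """Predict transfer competence of each deletion construct.

    A construct is ``functional`` when it retains both required features
    (the conserved 20-mer and REPT1) plus the enhancer region REPT2;
    ``attenuated`` when it retains the required features but not the
    enhancer (transfer detectable, roughly two orders of magnitude lower);
    ``nonfunctional`` otherwise.

    ``constructs`` is a mapping name -> intervals (or -> (intervals, label);
    extra payload is ignored) or a list of (name, intervals).
    """
    features = ORIT_FEATURES if features is None else features
    for label in (*required, enhancer):
        if label not in features:
            raise KeyError(f"rule refers to unknown feature label {label!r}")

    if isinstance(constructs, dict):
        items = list(constructs.items())
    else:
        items = list(constructs)
    calls = []
    for name, payload in items:
        intervals = payload[0] if isinstance(payload, tuple) and payload and isinstance(payload[0], list) else payload
        intervals = tuple(tuple(iv) for iv in intervals)
        retains = {f: _interval_subset(iv, intervals) for f, iv in features.items()}
        if all(retains[f] for f in required):
            cls = "functional" if retains[enhancer] else "attenuated"
        else:
            cls = "nonfunctional"
        calls.append(ConstructCall(name, intervals, retains, cls))
    return calls


def essential_region(
    functional: list[ConstructCall], nonfunctional: list[ConstructCall] = ()
) -> EssentialRegion:
    """Intersect the retained regions of all transfer-competent constructs.

    The result is the minimal interval every functional construct keeps —
    the essential region. An empty intersection, or one broken into several
    pieces, is an inconsistent series and raises. If a nonfunctional
    construct fully contains the result the series contradicts itself and a
    warning is issued.
    """
    if not functional:
        raise ValueError("at least one functional construct is required")
    inter = _merge(functional[0].retained)
    for c in functional[1:]:
        inter = _intersect_unions(inter, _merge(c.retained))
        if not inter:
            raise ValueError("functional constructs have an empty intersection")
    if len(inter) != 1:
        raise ValueError(f"essential region is not contiguous: {inter}")
    s, e = inter[0]
    region = EssentialRegion(s, e)
    for c in nonfunctional:
        if _interval_subset((s, e), c.retained):
            warn(
                f"nonfunctional construct {c.name} fully contains the essential "
                f"region [{s},{e}]: the series is internally inconsistent"
            )
    return region


def _merge(intervals):
    out = []
    for s, e in sorted(intervals):
        if out and s <= out[-1][1] + 1:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def _intersect_unions(a, b):
    out = []
    for s1, e1 in a:
        for s2, e2 in b:
            s, e = max(s1, s2), min(e1, e2)
            if s <= e:
                out.append((s, e))
    return _merge(out)


# ---------------------------------------------------------------------------
# Repeat integrity after mutation
# ---------------------------------------------------------------------------

def ir_integrity(
    seq: str,
    ir: InvertedRepeat,
    mutations: list[tuple[int, str]],
    tolerance: int = 1,
) -> tuple[bool, int]:
    """Re-evaluate arm complementarity after base substitutions.

    ``mutations`` are (1-based position, new base). Returns
    ``(still_ir, arm_mismatches)`` with ``still_ir`` true when the mutated
    arms pair with at most ``tolerance`` mismatches — symmetric mutations
    that preserve complementarity leave the count unchanged.
    """
    s = list(seq.upper())
    for pos, base in mutations:
        if not 1 <= pos <= len(s):
            raise ValueError(f"mutation position {pos} outside the sequence")
        s[pos - 1] = base.upper()
    mutated = "".join(s)
    left, right = ir.arms(mutated)
    mm = hamming(left, revcomp(right))
    return mm <= tolerance, mm


def construct_calls_to_frame(calls: list[ConstructCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        row = {"name": c.name, "predicted_class": c.predicted_class,
               "transfer_detectable": c.transfer_detectable}
        row.update({f"retains_{k}": v for k, v in c.retains.items()})
        rows.append(row)
    return pd.DataFrame(rows)
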