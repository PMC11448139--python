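"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the package's data structures and
algorithms: seed placement is found by naive substring scanning, window
scores by direct sliding-window comparison, so agreement with the package
is a genuine cross-check.
"""

import numpy as np
import pytest

from icemob.core import revcomp
from icemob.synthetic_data import SimConfig, make_integrated_genome


@pytest.fixture(scope="session")
def toy_config():
    return SimConfig(host_length=300, ice_length=1000, rng_seed=1)


@pytest.fixture(scope="session")
def toy_genome(toy_config):
    return make_integrated_genome(toy_config)


@pytest.fixture(scope="session")
def default_genome():
    return make_integrated_genome(SimConfig(rng_seed=7))


# ---------------------------------------------------------------------------
# Brute-force paired-seed mapper (oracle for pair_mapper.map_pair)
# ---------------------------------------------------------------------------

def _occurrences(text: str, sub: str):
    out, i = [], text.find(sub)
    while i != -1:
        out.append(i)
        i = text.find(sub, i + 1)
    return out


def brute_force_map(seq: str, seq1: str, seq2: str, k: int = 21,
                    min_dist: int = 20, max_dist: int = 2000):
    """Exhaustive seed placement by substring scan, same distance rule.

    Returns (status, span, distance, n_valid) where span is (start, end) or
    None, mirroring the contract of ``pair_mapper.map_pair``.
    """
    s1, s2 = seq1[:k].upper(), seq2[:k].upper()
    hits = {}
    for name, s in (("r1", s1), ("r2", s2)):
        if "N" in s:
            hits[name] = []
            continue
        fwd = [(p + 1, "+") for p in _occurrences(seq, s)]
        rev = [(p + 1, "-") for p in _occurrences(seq, revcomp(s))]
        hits[name] = fwd + rev
    if not hits["r1"] or not hits["r2"]:
        return "unmapped", None, None, 0
    spans = set()
    for a, b in (("r1", "r2"), ("r2", "r1")):
        for p, ps in hits[a]:
            for q, qs in hits[b]:
                if ps == "+" and qs == "-" and p <= q + k - 1:
                    spans.add((p, q + k - 1))
    if not spans:
        return "unmapped", None, None, 0
    valid = [(s, e) for s, e in spans if min_dist <= e - s + 1 <= max_dist]
    if not valid:
        return "distance_violation", None, None, 0
    dmin = min(e - s + 1 for s, e in valid)
    winners = [(s, e) for s, e in valid if e - s + 1 == dmin]
    if len(winners) > 1:
        return "ambiguous", None, None, len(valid)
    return "mapped", winners[0], dmin, len(valid)


def random_dna_str(n: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))
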