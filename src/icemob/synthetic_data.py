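"""Synthetic genomes, regulatory regions, read pairs and excision mixtures.

Everything downstream of raw sequencing is testable offline against data
built here: a host chromosome carrying an integrated element flanked by
identical direct repeats, planted regulatory motifs, paired-end reads drawn
from weighted templates with a truncated-normal insert distribution, and
integrated/excised template mixtures at a programmed excision fraction.

Determinism contract: one root seed in :class:`SimConfig`; child generators
are spawned per operation in a fixed order (host sequence, element payload,
read simulation, qPCR noise), so identical configs give byte-identical
outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import excision_model
from .core import Feature, GenomeRecord, revcomp

_BASES = np.frombuffer(b"ACGT", dtype="S1")

ATT_REPEAT = "GATTTTAAG"  # the 9-bp attL/attR direct repeat of ICE_KKS102_Tn4677


@dataclass
class SimConfig:
    """Parameters of the simulated study system.

    Insert-size defaults (mean 300, sd 50) are a generic short-insert
    paired-end library; real library metrics are not published for this
    system, and both are exposed here.
    """

    host_length: int = 5000
    ice_length: int = 3000
    att_repeat: str = ATT_REPEAT
    excision_fraction: float = 0.0
    expression_weights: dict[str, float] = field(default_factory=dict)
    read_length: int = 75
    insert_mean: float = 300.0
    insert_sd: float = 50.0
    n_pairs: int = 1000
    rng_seed: int = 0
    error_rate: float = 0.0  # per-base substitution probability

    def __post_init__(self):
        if not 0.0 <= self.excision_fraction <= 1.0:
            raise ValueError("excision_fraction must be in [0, 1]")
        if self.insert_mean < 20:
            raise ValueError("insert_mean must be >= 20 (the mappable minimum span)")
        if not self.att_repeat:
            raise ValueError("att_repeat must be nonempty")
        if any(w < 0 for w in self.expression_weights.values()):
            raise ValueError("expression weights must be nonnegative")

    def _child_rngs(self) -> dict[str, np.random.Generator]:
        """Per-operation child generators, spawned in a documented order."""
        kids = np.random.SeedSequence(self.rng_seed).spawn(4)
        names = ("host", "element", "reads", "panel")
        return {n: np.random.default_rng(s) for n, s in zip(names, kids)}


def random_dna(n: int, rng: np.random.Generator) -> str:
    return rng.choice(_BASES, size=n).tobytes().decode()


# ---------------------------------------------------------------------------
# Genome construction
# ---------------------------------------------------------------------------

def _unique_kmer_stream(n: int, k: int, rng: np.random.Generator) -> str:
    """Random DNA of length n in which every k-mer occurs exactly once.

    Built base by base, rejecting any base whose new k-mer has been seen
    (backtracking when all four are taken). With 4^k comfortably above n the
    greedy walk essentially never backtracks. Such a sequence contains no
    direct repeat of length >= k, which keeps a planted boundary repeat of
    length k the unambiguous longest repeat in the final genome.
    """
    if 4**k < 8 * n:
        raise ValueError(
            f"repeat length {k} is too short to be an unambiguous boundary "
            f"in a {n}-bp background"
        )
    bases = "ACGT"
    seq = list(random_dna(k, rng))
    used = {"".join(seq)}
    while len(seq) < n:
        tail = "".join(seq[-(k - 1) :])
        for b in rng.permutation(4):
            cand = tail + bases[b]
            if cand not in used:
                used.add(cand)
                seq.append(bases[b])
                break
        else:  # dead end: step back (the blocking k-mer stays blocked)
            seq.pop()
    return "".join(seq)


def _place_genes(offset: int, total: int, names: list[str]) -> list[Feature]:
    """Evenly tile gene features across [offset+1, offset+total]."""
    feats = []
    n = len(names)
    slot = total // n
    for i, name in enumerate(names):
        start = offset + i * slot + slot // 10 + 1
        end = min(offset + (i + 1) * slot - slot // 10, offset + total)
        feats.append(Feature(name, start, end, "+", "gene"))
    return feats


def make_integrated_genome(cfg: SimConfig) -> GenomeRecord:
    """Host chromosome with the element integrated between two repeat copies.

    Layout: upstream host — repeat (attL) — element payload — repeat (attR)
    — downstream host. The background (host and payload) carries no repeated
    k-mer of the boundary-repeat length, and the assembly is verified so that
    the att pair is the genome's unique longest direct repeat — repeat
    detection on the product is therefore unambiguous. Genes are tiled both
    inside the element (xis, int, traI, traG, traR) and outside (rrn, hostA).
    """
    from .excision_model import _longest_repeated_pair

    rep = cfg.att_repeat.upper()
    r = len(rep)
    if cfg.ice_length <= 2 * r:
        raise ValueError("ice_length must exceed twice the repeat length")
    rngs = cfg._child_rngs()
    ins = cfg.host_length // 2
    total_bg = cfg.host_length + cfg.ice_length
    for _ in range(50):
        stream = _unique_kmer_stream(total_bg, r, rngs["host"])
        if rep in stream:
            continue
        upstream = stream[:ins]
        payload = stream[ins : ins + cfg.ice_length]
        downstream = stream[ins + cfg.ice_length :]
        seq = upstream + rep + payload + rep + downstream
        # junction k-mers can create chance repeats; accept only when the
        # longest direct repeat pair is exactly the att pair
        hit = _longest_repeated_pair(seq, min(6, r))
        if hit == (rep, ins, ins + r + cfg.ice_length):
            break
    else:
        raise RuntimeError("could not assemble a genome with an unambiguous boundary repeat")
    attL = Feature("attL", ins + 1, ins + r, "+", "attL")
    attR = Feature("attR", ins + r + cfg.ice_length + 1, ins + 2 * r + cfg.ice_length, "+", "attR")

    feats = [attL, attR]
    feats += _place_genes(0, ins, ["rrn"])
    feats += _place_genes(ins + r, cfg.ice_length, ["xis", "int", "traI", "traG", "traR"])
    feats += _place_genes(ins + r + cfg.ice_length + r, cfg.host_length - ins, ["hostA"])
    genome = GenomeRecord(id="sim_integrated", seq=seq, features=feats)
    assert genome.seq.count(rep) == 2, "boundary repeat must be unique to the att sites"
    return genome


def plant_motifs(
    genome: GenomeRecord, plants: list[tuple[str, int, str]]
) -> GenomeRecord:
    """Overwrite sequence with motifs at given 1-based positions.

    ``plants``: list of (name, start, motif_seq). Each planted motif is
    recorded as a ``motif`` feature so scanners can be checked against the
    recorded coordinates.
    """
    seq = list(genome.seq)
    feats = list(genome.features)
    for name, start, motif in plants:
        end = start + len(motif) - 1
        if not (1 <= start and end <= len(seq)):
            raise ValueError(f"motif {name} does not fit at position {start}")
        seq[start - 1 : end] = motif.upper()
        feats.append(Feature(name, start, end, "+", "motif"))
    return GenomeRecord(id=genome.id, seq="".join(seq), features=feats, circular=genome.circular)


def make_excision_mixture(
    integrated: GenomeRecord, fraction: float
) -> list[tuple[GenomeRecord, float]]:
    """Templates present in a partially excised population.

    Returns ``[(integrated, 1 - fraction), (attB chromosome, fraction),
    (attP circle, fraction)]``; the products come from the recombination
    model, so length conservation holds by construction.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    for need in ("attL", "attR"):
        if not integrated.get_features(kind=need):
            raise ValueError(f"integrated genome lacks an {need} feature")
    aL = integrated.get_features(kind="attL")[0]
    aR = integrated.get_features(kind="attR")[0]
    products = excision_model.excise(integrated, (aL.start, aL.end), (aR.start, aR.end))
    return [
        (integrated, 1.0 - fraction),
        (products.chromosome, fraction),
        (products.circle, fraction),
    ]


def make_orit_region(rng_seed: int = 0, length: int = 463) -> tuple[GenomeRecord, list[str]]:
    """Synthetic stand-in for the 463-bp traF-traI intergenic (oriT) region.

    The real sequence is not redistributable here, so a random background is
    decorated with the features the region is known to carry, at the fixture
    coordinates of :data:`icemob.orit_analyzer.ORIT_FEATURES`: perfect
    inverted repeats at REPT1/2/3, a 20-bp "conserved" window containing the
    CAAAAGG half-site, and T-N11-A LysR motifs. Returns the region plus
    three homolog sequences that share the conserved window exactly but are
    otherwise randomised — so conserved-window discovery has a planted truth.
    """
    from .orit_analyzer import ORIT_FEATURES

    rng = np.random.default_rng(np.random.SeedSequence(rng_seed).spawn(2)[0])
    seq = list(random_dna(length, rng))

    def put(start, frag):
        seq[start - 1 : start - 1 + len(frag)] = list(frag)

    def palindrome(span):
        s, e = span
        n = e - s + 1
        arm = (n - 3) // 2  # leaves a loop of 3-4 nt
        left = random_dna(arm, rng)
        loop = random_dna(n - 2 * arm, rng)
        return left + loop + revcomp(left)

    feats = []
    for name, (s, e) in ORIT_FEATURES.items():
        if name.startswith("REPT"):
            put(s, palindrome((s, e)))
            feats.append(Feature(name, s, e, "+", "REPT"))
        elif name == "conserved20":
            core20 = "TGT" + "CAAAAGG" + random_dna(10, rng)
            put(s, core20)
            feats.append(Feature(name, s, e, "+", "oriT_core"))
        else:  # LysR motifs: plant a T-N11-A with 6-bp complementary arms
            arm = "CGTTTT"
            site = arm + random_dna(11, rng) + revcomp(arm)
            put(s, site)
            feats.append(Feature(name, s, s + len(site) - 1, "+", "motif"))
    region = GenomeRecord(id="synthetic_oriT_region", seq="".join(seq), features=feats)

    c20_s, c20_e = ORIT_FEATURES["conserved20"]
    conserved = region.subseq(c20_s, c20_e)
    homologs = []
    for i in range(3):
        h = list(random_dna(length, rng))
        pos = int(rng.integers(0, length - 20))
        h[pos : pos + 20] = list(conserved)
        homologs.append("".join(h))
    return region, homologs


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimulatedPair:
    """A read pair plus its ground truth placement."""

    id: str
    seq1: str
    seq2: str
    template_id: str
    start: int  # 1-based fragment interval on the template (may exceed
    end: int    # template length on circular templates; stored pre-modulo)


def _truncnorm_int(mean, sd, lo, hi, rng) -> int:
    """Rejection-sampled integer from Normal(mean, sd) clipped to [lo, hi]."""
    if lo > hi:
        raise ValueError("empty fragment-length support")
    for _ in range(1000):
        x = int(round(rng.normal(mean, sd)))
        if lo <= x <= hi:
            return x
    return int(min(max(round(mean), lo), hi))


def simulate_read_pairs(
    genome_mix: list[tuple[GenomeRecord, float]], cfg: SimConfig
) -> list[SimulatedPair]:
    """Draw error-free (by default) read pairs from weighted templates.

    A fragment source is chosen with probability proportional to
    ``template_weight x expression_weight`` of each expressed feature (names
    listed in ``cfg.expression_weights``; features absent from the map are
    not sampled). The fragment length follows Normal(insert_mean, insert_sd)
    truncated to [read_length, template length] and is placed uniformly among
    positions overlapping the chosen feature. Read 1 is the fragment 5' end
    on the forward strand; read 2 is the reverse complement of the fragment
    3' end. Circular templates may yield fragments across the origin (truth
    intervals then extend past the template length and wrap modulo its
    length).
    """
    if cfg.read_length < 21:
        raise ValueError("read_length must be >= 21")
    weights = []
    sources = []  # (template, feature)
    for genome, w in genome_mix:
        if w < 0:
            raise ValueError("template weights must be nonnegative")
        if w == 0:
            continue
        for f in genome.features:
            ew = cfg.expression_weights.get(f.name, 0.0)
            if ew > 0:
                sources.append((genome, f))
                weights.append(w * ew)
    if not sources:
        raise ValueError("no template/feature combination has positive weight")
    p = np.asarray(weights, float)
    p /= p.sum()

    rng = cfg._child_rngs()["reads"]
    out = []
    for i in range(cfg.n_pairs):
        src = rng.choice(len(sources), p=p)
        genome, feat = sources[src]
        L = len(genome)
        flen = _truncnorm_int(cfg.insert_mean, cfg.insert_sd, cfg.read_length, L, rng)
        # fragment start uniform among placements overlapping the feature
        lo = max(1, feat.start - flen + 1)
        hi = min(feat.end, L - flen + 1) if not genome.circular else feat.end
        if hi < lo:
            lo, hi = 1, max(1, L - flen + 1)  # feature cannot anchor this length
        start = int(rng.integers(lo, hi + 1))
        end = start + flen - 1
        frag = genome.subseq(start, end)
        r1 = frag[: cfg.read_length]
        r2 = revcomp(frag)[: cfg.read_length]
        if cfg.error_rate > 0:
            r1 = _mutate(r1, cfg.error_rate, rng)
            r2 = _mutate(r2, cfg.error_rate, rng)
        out.append(SimulatedPair(f"pair_{i:06d}", r1, r2, genome.id, start, end))
    return out


def _mutate(read: str, rate: float, rng: np.random.Generator) -> str:
    arr = np.frombuffer(read.encode(), dtype="S1").copy()
    hit = rng.random(len(arr)) < rate
    if hit.any():
        subs = rng.choice(_BASES, size=int(hit.sum()))
        arr[hit] = subs  # may resample the same base; rate is an upper bound
    return arr.tobytes().decode()


# ---------------------------------------------------------------------------
# qPCR panel simulation
# ---------------------------------------------------------------------------

def simulate_qpcr_panel(
    fractions: dict, total_copies: float = 1e6, noise_cv: float = 0.1, rng_seed: int = 0
) -> pd.DataFrame:
    """Raw qPCR copy numbers for an excision time course.

    ``fractions``: timepoint -> excision fraction. Per timepoint the template
    DNA amount is scaled by a random factor (emulating extraction variation,
    which the internal standard corrects), attP and attB copies equal
    ``total x fraction``, total-element copies (set_c) equal ``total``, and
    every measurement carries multiplicative lognormal noise of coefficient
    of variation ``noise_cv``.
    """
    rng = np.random.default_rng(np.random.SeedSequence(rng_seed).spawn(4)[3])
    sigma = np.sqrt(np.log1p(noise_cv**2))
    rows = []
    for t, frac in sorted(fractions.items()):
        scale = rng.uniform(0.5, 2.0)  # per-sample DNA amount variation
        for target, copies in (
            ("set_a", total_copies * frac),
            ("set_b", total_copies * frac),
            ("set_c", total_copies),
        ):
            noisy = copies * scale * rng.lognormal(-sigma**2 / 2, sigma)
            rows.append((target, t, noisy))
    return pd.DataFrame(rows, columns=["target", "timepoint", "value"])


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def write_fastq_pair(pairs: list[SimulatedPair], prefix) -> tuple[str, str]:
    """Write paired FASTQ files ``<prefix>_R1.fastq`` / ``<prefix>_R2.fastq``.

    Base qualities are constant Phred33 'I' (Q40); they are unused downstream.
    """
    p1, p2 = f"{prefix}_R1.fastq", f"{prefix}_R2.fastq"
    with open(p1, "w") as f1, open(p2, "w") as f2:
        for p in pairs:
            f1.write(f"@{p.id}/1\n{p.seq1}\n+\n{'I' * len(p.seq1)}\n")
            f2.write(f"@{p.id}/2\n{p.seq2}\n+\n{'I' * len(p.seq2)}\n")
    return p1, p2


def write_truth_table(pairs: list[SimulatedPair], path) -> None:
    pd.DataFrame(
        [(p.id, p.template_id, p.start, p.end) for p in pairs],
        columns=["pair_id", "template_id", "start", "end"],
    ).to_csv(path, sep="\t", index=False)
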