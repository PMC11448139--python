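# icemob

Sequence-analysis toolkit for integrative and conjugative elements (ICEs) of
the Tn*4371* family, built around the biology of ICE_KKS102_Tn*4677* from
*Acidovorax* sp. KKS102: a 61.8-kb element flanked by 9-bp `attL`/`attR`
direct repeats (`GATTTTAAG`) whose excision, conjugative transfer and
regulation by the LysR-type activator TraR can all be interrogated from
sequence. The package is aimed at microbial-genomics researchers who want to
run the complete computational side of such a study offline: no downloads are
needed because a first-class synthetic-data generator reproduces every input
structure the analyses assume.

## What it computes

* **`synthetic_data`** — host chromosomes with an integrated element flanked
  by identical direct repeats (guaranteed to be the genome's unique longest
  direct repeat), planted regulatory motifs, paired-end reads with truth
  intervals, excision mixtures, and noisy qPCR panels.
* **`pair_mapper`** — an exact-seed paired-read mapper: each read is anchored
  by its initial 21-mer at 100 % identity, pairs are placed inward-facing on
  opposite strands with an end-to-end distance of 20–2,000 bp, the shortest
  distance wins, and ties are reported as ambiguous. Each mapped span counts
  as one transcript for every gene it overlaps; expression is compared
  between conditions after normalising to a reference gene (*rrn*):
  `fold(g) = (b_g / b_ref) / (a_g / a_ref)`.
* **`motif_scanner`** — the LysR T-N<sub>11</sub>-A motif (conserved T and A
  with an 11-nt spacer inside an interrupted inverted repeat), mismatch-
  tolerant similarity search, dyad half-sites (`CAAAACG` and variants),
  sigma-70 −35/−10 promoter boxes by an additive homology score with a
  15–21-bp spacer, and the "binding site immediately upstream of the −35
  box" architecture test. The five published sites of this system are
  packaged as `BINDING_SITES` and re-detected with `arm_len=6,
  max_arm_mismatch≤3` (full sites) and `max_mismatch≤1` (half-sites).
* **`orit_analyzer`** — inverted-repeat (REPT) detection with a mismatch
  budget, best-conserved 20-bp window discovery across homologous regions,
  deletion-construct classification (functional ⇔ retains the conserved
  20-mer **and** REPT1; attenuated when REPT2 is additionally lost), and the
  essential-region intersection of the functional constructs.
* **`excision_model`** — att-site recombination: boundary-repeat detection,
  `excise`/`integrate` with exact length conservation and feature
  remapping, qPCR primer-set placement logic (set a → circular form only,
  set b → vacated attB site only, set c → both element forms) and
  internal-standard-normalised relative quantification of excision.

## Worked example

```python
from icemob.synthetic_data import SimConfig, make_integrated_genome
from icemob.excision_model import detect_boundary_repeat, excise
from icemob.motif_scanner import BINDING_SITES, find_tn11a

genome = make_integrated_genome(SimConfig(host_length=300, ice_length=1000, rng_seed=1))
print(len(genome))                      # 1318  (300 host + 1000 element + 2 x 9 repeats)

repeat, attL, attR = detect_boundary_repeat(genome)
print(repeat, attL, attR)               # GATTTTAAG (151, 159) (1160, 1168)

products = excise(genome, attL, attR)
print(len(products.circle), len(products.chromosome))   # 1009 309  (sum = 1318)

hit, = find_tn11a(BINDING_SITES["BSxis"], arm_len=6, max_arm_mismatch=1)
print(hit.t_pos, hit.a_pos, hit.spacer_len, hit.arm_mismatches)   # 6 18 11 0
```

The element excises into a 1,009-bp circle (payload plus one repeat copy at
the attP junction) and a 309-bp chromosome carrying attB; the xis-upstream
binding site holds one T-N<sub>11</sub>-A motif whose 6-bp arms (`CGTTTT` /
`AAAACG`) are perfect reverse complements.

A shell interface wraps the same functions:

```sh
icemob simulate --config config.yaml --outdir sim/
icemob map --genome sim/integrated.fasta --r1 sim/reads_R1.fastq \
           --r2 sim/reads_R2.fastq --features sim/features.tsv --out mapped/
icemob scan --fasta region.fa --tn11a --half-site CAAAACG --promoters --out hits.tsv
icemob excise --genome sim/integrated.fasta --out excised/
icemob qpcr --panel raw.csv --normalizer set_c --out panel.csv
```

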