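"""Recombination arithmetic, repeat detection, amplicon logic, qPCR maths."""

import numpy as np
import pandas as pd
import pytest
from conftest import random_dna_str
from hypothesis import given, settings
from hypothesis import strategies as st

from icemob.core import GenomeRecord
from icemob.excision_model import (
    PrimerPair,
    detect_boundary_repeat,
    excise,
    integrate,
    make_qpcr_primer_sets,
    predict_amplicons,
    quantify_excision,
)
from icemob.synthetic_data import SimConfig, make_integrated_genome, simulate_qpcr_panel


@pytest.fixture(scope="module")
def att_intervals(toy_genome):
    aL = toy_genome.get_features(kind="attL")[0]
    aR = toy_genome.get_features(kind="attR")[0]
    return (aL.start, aL.end), (aR.start, aR.end)


class TestBoundaryRepeat:
    def test_recovers_the_planted_nine_bp_repeat(self, toy_genome, att_intervals):
        rep, attL, attR = detect_boundary_repeat(toy_genome)
        assert rep == "GATTTTAAG" and len(rep) == 9
        assert (attL, attR) == att_intervals

    def test_longer_flanking_repeat_returned_in_full(self):
        g = make_integrated_genome(
            SimConfig(host_length=300, ice_length=1000, att_repeat="GATTTTAAGCAT", rng_seed=2)
        )
        rep, _, _ = detect_boundary_repeat(g)
        assert rep == "GATTTTAAGCAT"  # maximality: the full 12-mer, not a 9-mer

    def test_element_hint_restricts_search(self, toy_genome, att_intervals):
        (s1, _), (_, e2) = att_intervals
        rep, attL, attR = detect_boundary_repeat(toy_genome, element_hint=(s1, e2))
        assert rep == "GATTTTAAG" and (attL, attR) == att_intervals

    def test_absent_repeat_is_an_error(self):
        rng = np.random.default_rng(40)
        # unique-k-mer background has no repeated 9-mer at all
        from icemob.synthetic_data import _unique_kmer_stream

        seq = _unique_kmer_stream(800, 9, rng)
        with pytest.raises(ValueError, match="no direct repeat"):
            detect_boundary_repeat(GenomeRecord(id="r", seq=seq), min_len=9)


class TestExciseIntegrate:
    def test_product_lengths(self, toy_genome, att_intervals):
        attL, attR = att_intervals
        prod = excise(toy_genome, attL, attR)
        assert len(prod.circle) == 1009  # payload + one repeat copy
        assert len(prod.chromosome) == 309
        assert len(prod.circle) + len(prod.chromosome) == 1318

    def test_each_product_has_exactly_one_repeat_copy(self, toy_genome, att_intervals):
        prod = excise(toy_genome, *att_intervals)
        assert prod.circle.seq.count(prod.repeat_seq) == 1
        assert prod.circle.seq.startswith(prod.repeat_seq)  # attP junction first
        assert prod.chromosome.seq.count(prod.repeat_seq) == 1

    def test_attB_junction_is_host_left_repeat_host_right(self, toy_genome, att_intervals):
        (s1, _), (_, e2) = att_intervals
        prod = excise(toy_genome, *att_intervals)
        expected = toy_genome.seq[: s1 - 1] + prod.repeat_seq + toy_genome.seq[e2:]
        assert prod.chromosome.seq == expected

    def test_round_trip_is_byte_identical(self, toy_genome, att_intervals):
        (s1, e1), _ = att_intervals
        prod = excise(toy_genome, *att_intervals)
        attB = (s1, s1 + prod.repeat_len - 1)
        back = integrate(prod.circle, prod.chromosome, attB)
        assert back.seq == toy_genome.seq
        assert {(f.name, f.start, f.end) for f in back.get_features(kind="gene")} == {
            (f.name, f.start, f.end) for f in toy_genome.get_features(kind="gene")
        }

    def test_mismatched_att_sequences_rejected(self, toy_genome, att_intervals):
        (s1, e1), (s2, e2) = att_intervals
        with pytest.raises(ValueError, match="differ"):
            excise(toy_genome, (s1 + 1, e1 + 1), (s2, e2))

    def test_integrating_into_fresh_host_adds_circle_length(self, toy_genome, att_intervals):
        prod = excise(toy_genome, *att_intervals)
        rep = prod.repeat_seq
        rng = np.random.default_rng(41)
        host = random_dna_str(200, rng) + rep + random_dna_str(200, rng)
        host_rec = GenomeRecord(id="fresh", seq=host)
        product = integrate(prod.circle, host_rec, (201, 200 + len(rep)))
        assert len(product) == len(host_rec) + len(prod.circle)

    def test_element_feature_coordinates_shift_by_insertion_offset(
        self, toy_genome, att_intervals
    ):
        prod = excise(toy_genome, *att_intervals)
        (s1, _), _ = att_intervals
        back = integrate(prod.circle, prod.chromosome, (s1, s1 + prod.repeat_len - 1))
        xis_circle = prod.circle.require_feature("xis")
        xis_back = back.require_feature("xis")
        assert xis_back.start == xis_circle.start + s1 - 1

    @settings(deadline=None, derandomize=True, max_examples=20)
    @given(st.integers(0, 2**31 - 1))
    def test_conservation_on_random_fixtures(self, seed):
        g = make_integrated_genome(SimConfig(host_length=200, ice_length=400, rng_seed=seed))
        aL = g.get_features(kind="attL")[0]
        aR = g.get_features(kind="attR")[0]
        prod = excise(g, (aL.start, aL.end), (aR.start, aR.end))
        assert len(prod.circle) + len(prod.chromosome) == len(g)
        back = integrate(prod.circle, prod.chromosome, (aL.start, aL.end))
        assert back.seq == g.seq


@pytest.fixture(scope="module")
def panel_templates(toy_genome, att_intervals):
    prod = excise(toy_genome, *att_intervals)
    primers = make_qpcr_primer_sets(toy_genome, *att_intervals)
    return toy_genome, prod, primers


class TestAmplicons:
    def test_set_a_amplifies_only_the_circle(self, panel_templates):
        g, prod, primers = panel_templates
        tab = predict_amplicons([g, prod.chromosome, prod.circle], primers)
        assert pd.isna(tab.loc[g.id, "set_a"])
        assert pd.isna(tab.loc[prod.chromosome.id, "set_a"])
        assert tab.loc[prod.circle.id, "set_a"] > 0

    def test_set_b_amplifies_only_the_attB_chromosome(self, panel_templates):
        g, prod, primers = panel_templates
        tab = predict_amplicons([g, prod.chromosome, prod.circle], primers)
        assert pd.isna(tab.loc[g.id, "set_b"])
        assert tab.loc[prod.chromosome.id, "set_b"] > 0
        assert pd.isna(tab.loc[prod.circle.id, "set_b"])

    def test_set_c_amplifies_integrated_and_circle(self, panel_templates):
        g, prod, primers = panel_templates
        tab = predict_amplicons([g, prod.chromosome, prod.circle], primers)
        assert tab.loc[g.id, "set_c"] > 0
        assert tab.loc[prod.circle.id, "set_c"] > 0

    def test_circle_product_spans_the_junction(self, panel_templates):
        g, prod, primers = panel_templates
        set_a = next(p for p in primers if p.name == "set_a")
        # forward primer lies before the junction on the circle rotation,
        # so the product must wrap the origin
        assert prod.circle.seq.find(set_a.fwd) > len(prod.circle) - set_a.max_product

    def test_duplicated_primer_site_flagged_nonspecific(self):
        rng = np.random.default_rng(42)
        fwd, rev_site = random_dna_str(20, rng), random_dna_str(20, rng)
        insert = random_dna_str(40, rng)
        seq = fwd + insert + rev_site + random_dna_str(30, rng) + fwd + insert + rev_site
        from icemob.core import revcomp

        primer = PrimerPair("dup", fwd, revcomp(rev_site), 200)
        tab = predict_amplicons([GenomeRecord(id="t", seq=seq)], [primer])
        assert tab.loc["t", "dup"] == "nonspecific"

    def test_short_primer_rejected(self):
        with pytest.raises(ValueError, match="15"):
            PrimerPair("x", "ACGTACGT", "ACGTACGTACGTACGTACGT")


class TestQuantification:
    @staticmethod
    def _panel(rows):
        return pd.DataFrame(rows, columns=["target", "timepoint", "value"])

    def test_constant_raw_values_give_unit_fold(self):
        rows = [(t, tp, 5.0) for t in ("set_a", "set_c") for tp in (0, 12, 24)]
        q = quantify_excision(self._panel(rows))
        assert all(v == 1.0 for v in q.fold_change["set_a"].values())

    def test_doubling_attp_with_constant_normalizer_gives_fold_two(self):
        rows = [("set_a", 0, 3.0), ("set_a", 12, 6.0), ("set_c", 0, 9.0), ("set_c", 12, 9.0)]
        q = quantify_excision(self._panel(rows))
        assert q.fold_change["set_a"][12] == pytest.approx(2.0)

    def test_scale_invariance_per_timepoint(self):
        rows = [("set_a", 0, 2.0), ("set_a", 12, 8.0), ("set_c", 0, 4.0), ("set_c", 12, 5.0)]
        scaled = [(t, tp, v * (10.0 if tp == 12 else 3.0)) for t, tp, v in rows]
        q1 = quantify_excision(self._panel(rows))
        q2 = quantify_excision(self._panel(scaled))
        assert q1.fold_change == q2.fold_change

    def test_zero_at_first_timepoint_is_an_error(self):
        rows = [("set_a", 0, 0.0), ("set_a", 12, 6.0), ("set_c", 0, 9.0), ("set_c", 12, 9.0)]
        with pytest.raises(ValueError, match="first timepoint"):
            quantify_excision(self._panel(rows))

    def test_nonpositive_normalizer_is_an_error(self):
        rows = [("set_a", 0, 1.0), ("set_c", 0, 0.0)]
        with pytest.raises(ValueError, match="positive"):
            quantify_excision(self._panel(rows))

    def test_simulated_hundredfold_sweep_recovered_within_twofold(self):
        """Programmed 100x excision increase recovered from a noisy panel."""
        panel = simulate_qpcr_panel({0: 1e-5, 12: 1e-4, 24: 1e-3}, rng_seed=43)
        q = quantify_excision(panel)
        for target in ("set_a", "set_b"):
            fold = q.fold_change[target][24]
            assert 50 <= fold <= 200
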