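import math
import random

import numpy as np
import pytest
from Bio.SeqUtils.ProtParamData import DIWV
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import brute_cooccurrence
from protclass.features import (
    DEFAULT_PK,
    FEATURE_NAMES,
    aa_composition,
    aromaticity,
    cooccurrence_entropy_energy,
    extract_features,
    feature_matrix,
    gravy,
    instability_index,
    is_unstable,
    isoelectric_point,
    net_charge,
    nominal_mass,
)
from protclass.io import CANONICAL_AA, ProteinRecord

sequences = st.text(alphabet=CANONICAL_AA, min_size=1, max_size=60)


class TestComposition:
    def test_uniform_sequence(self):
        comp, groups, length = aa_composition(CANONICAL_AA)
        assert np.allclose(comp, 0.05)
        assert length == 20

    def test_homopolymer(self):
        comp, _, _ = aa_composition("AAAA")
        assert comp[0] == 1.0 and comp[1:].sum() == 0.0

    def test_charged_groups(self):
        _, groups, _ = aa_composition("KRDE")
        # groups: positive, negative, polar, nonpolar, aromatic
        assert groups[0] == 0.5 and groups[1] == 0.5
        assert groups[2] == groups[3] == groups[4] == 0.0

    @settings(max_examples=50, derandomize=True)
    @given(sequences)
    def test_fractions_sum_to_one(self, seq):
        comp, _, length = aa_composition(seq)
        assert comp.sum() == pytest.approx(1.0, abs=1e-9)
        assert length == len(seq)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            aa_composition("")


class TestSimpleDescriptors:
    def test_aromaticity(self):
        assert aromaticity("FWY") == pytest.approx(1.0)
        assert aromaticity("AAAA") == pytest.approx(0.0)
        assert aromaticity("AFWYA") == pytest.approx(0.6)

    def test_gravy_hand_summed_kyte_doolittle(self):
        # published hydropathies: A = 1.8, I = 4.5
        assert gravy("AI") == pytest.approx((1.8 + 4.5) / 2)
        assert gravy("RRRR") == pytest.approx(-4.5)

    @settings(max_examples=30, derandomize=True)
    @given(sequences)
    def test_gravy_order_free(self, seq):
        assert gravy(seq) == pytest.approx(gravy(seq[::-1]), abs=1e-9)

    def test_instability_length_two_reduces_to_single_weight(self):
        assert instability_index("AW") == pytest.approx(5 * DIWV["A"]["W"])

    def test_instability_alternating_dipeptide_brute_force(self):
        seq = "AW" * 5
        expected = (10 / len(seq)) * sum(
            DIWV[seq[i]][seq[i + 1]] for i in range(len(seq) - 1)
        )
        assert instability_index(seq) == pytest.approx(expected)

    def test_unstable_flag_above_40(self):
        # Arg-Arg dipeptides carry the largest destabilizing weight (58.28)
        assert instability_index("R" * 10) == pytest.approx(9 * 58.28)
        assert is_unstable("R" * 10)
        assert not is_unstable("A" * 10)

    def test_nominal_mass_glycine(self):
        assert nominal_mass("G") == 75  # residue 57 + water 18

    def test_nominal_mass_concatenation_water_bookkeeping(self):
        a, b = "ACDEF", "GHIKL"
        assert nominal_mass(a + b) == nominal_mass(a) + nominal_mass(b) - 18

    @settings(max_examples=30, derandomize=True)
    @given(sequences)
    def test_nominal_mass_permutation_invariant(self, seq):
        shuffled = "".join(sorted(seq))
        assert nominal_mass(seq) == nominal_mass(shuffled)


class TestChargeAndPI:
    def test_net_charge_monotone_decreasing_in_pH(self):
        rng = random.Random(5)
        for _ in range(10):
            seq = "".join(rng.choice(CANONICAL_AA) for _ in range(30))
            values = [net_charge(seq, ph) for ph in np.linspace(0, 14, 30)]
            assert all(x > y for x, y in zip(values, values[1:]))

    def test_single_residue_pI_is_terminal_midpoint(self):
        # only the two termini ionize: charge is antisymmetric about the
        # midpoint of their pK values, so pI = (8.6 + 3.6) / 2 exactly
        expected = (DEFAULT_PK["Nterm"] + DEFAULT_PK["Cterm"]) / 2
        assert isoelectric_point("A") == pytest.approx(expected, abs=1e-3)

    def test_net_charge_of_glycine_hand_evaluated(self):
        expected = 1 / (1 + 10 ** (7.2 - 8.6)) - 1 / (1 + 10 ** (3.6 - 7.2))
        assert net_charge("G", 7.2) == pytest.approx(expected, abs=1e-6)

    @settings(max_examples=20, derandomize=True)
    @given(sequences)
    def test_pI_is_a_zero_crossing(self, seq):
        pi = isoelectric_point(seq)
        assert abs(net_charge(seq, pi)) < 0.01
        assert net_charge(seq, pi - 0.1) > net_charge(seq, pi + 0.1)


class TestCooccurrence:
    def test_homopolymer_degenerate_distribution(self):
        entropy, energy = cooccurrence_entropy_energy("A" * 9)
        assert entropy == 0.0 and energy == 1.0

    def test_short_sequence_yields_zeros_with_warning(self, caplog):
        with caplog.at_level("WARNING", logger="protclass.features"):
            assert cooccurrence_entropy_energy("ACDEFGHI") == (0.0, 0.0)
        assert "length 8" in caplog.text

    def test_twelve_residue_toy_matches_brute_force(self):
        seq = "ACDEFGHIKLMN"
        entropy, energy = cooccurrence_entropy_energy(seq)
        exp_entropy, exp_energy = brute_cooccurrence(seq)
        assert entropy == pytest.approx(exp_entropy)
        assert energy == pytest.approx(exp_energy)

    @settings(max_examples=100, derandomize=True)
    @given(st.text(alphabet=CANONICAL_AA, min_size=9, max_size=40))
    def test_bounds(self, seq):
        entropy, energy = cooccurrence_entropy_energy(seq)
        assert 0.0 < energy <= 1.0
        assert 0.0 <= entropy <= math.log2(400)

    def test_exhaustive_three_letter_sample(self):
        # spot sample here; the exhaustive sweep runs in the acceptance suite
        rng = random.Random(0)
        for _ in range(200):
            seq = "".join(rng.choice("ACD") for _ in range(rng.randint(9, 12)))
            assert cooccurrence_entropy_energy(seq) == pytest.approx(
                brute_cooccurrence(seq)
            )


class TestFeatureVector:
    CONSENSUS = "ACDEFGHIKLMNPQRSTVWY" * 2

    def test_record_equal_to_consensus(self):
        rec = ProteinRecord("r", self.CONSENSUS)
        fv = extract_features(rec, self.CONSENSUS)
        assert fv.selfalign_consensus == pytest.approx(1.0)
        assert fv.global_identity == pytest.approx(1.0)

    def test_vector_has_39_named_values(self):
        assert len(FEATURE_NAMES) == 39
        rec = ProteinRecord("r", "ACDEFGHIKLMNPQRSTVWY")
        assert extract_features(rec, self.CONSENSUS).to_array().shape == (39,)

    def test_identical_records_identical_vectors(self):
        a = ProteinRecord("a", "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ")
        b = ProteinRecord("b", a.sequence)
        df = feature_matrix([a, b], self.CONSENSUS)
        assert (df.loc["a"] == df.loc["b"]).all()

    def test_order_sensitive_vs_order_free_descriptors(self):
        seq = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQA"
        rev = seq[::-1]
        assert nominal_mass(seq) == nominal_mass(rev)
        assert gravy(seq) == pytest.approx(gravy(rev))
        assert aromaticity(seq) == pytest.approx(aromaticity(rev))
        # order-sensitive statistics change under reordering: reversal for
        # the (asymmetric) dipeptide weights, sorting for the pair texture
        assert instability_index(seq) != pytest.approx(instability_index(rev))
        assert cooccurrence_entropy_energy(seq) != pytest.approx(
            cooccurrence_entropy_energy("".join(sorted(seq)))
        )
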