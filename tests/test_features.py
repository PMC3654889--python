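import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from seqppi import (
    EncoderConfig,
    PairEncoder,
    encode_ac,
    encode_ct,
    encode_ctd_region,
    encode_ld,
    encode_mac,
    encode_pair,
    load_group_map,
    load_property_table,
    split_regions,
    standardize_table,
)
from seqppi.features import AMINO_ACIDS, pair_block_layout

from . import oracles

sequences = st.text(alphabet=AMINO_ACIDS, min_size=4, max_size=120)


class TestPropertyTable:
    def test_raw_values_match_published_table(self):
        raw = load_property_table(standardized=False)
        assert raw.loc["A", "hydrophobicity"] == 0.62
        assert raw.loc["A", "side_chain_volume"] == 27.5
        assert raw.loc["G", "side_chain_volume"] == 0.0
        assert raw.loc["W", "sasa"] == 2.663
        assert raw.loc["R", "hydrophobicity"] == -2.53
        assert raw.shape == (20, 6)

    def test_standardized_columns_zero_mean_unit_sd(self):
        table = load_property_table()
        assert np.all(np.abs(table.mean(axis=0)) < 1e-10)
        assert np.all(np.abs(table.std(axis=0, ddof=0) - 1) < 1e-10)

    def test_standardized_value_against_direct_mean_sd(self):
        raw = load_property_table(standardized=False)
        h = raw["hydrophobicity"].to_numpy()
        mean = sum(h) / 20
        sd = math.sqrt(sum((v - mean) ** 2 for v in h) / 20)
        expected = (0.62 - mean) / sd
        assert load_property_table().loc["A", "hydrophobicity"] == pytest.approx(
            expected, abs=1e-12
        )

    def test_zero_variance_column_rejected(self):
        raw = load_property_table(standardized=False).copy()
        raw["polarity"] = 1.0
        with pytest.raises(ValueError, match="zero-variance"):
            standardize_table(raw)


class TestGroupMap:
    def test_partitions_all_twenty_letters(self):
        groups = load_group_map()
        assert set(groups) == set(AMINO_ACIDS)
        by_group = {}
        for aa, g in groups.items():
            by_group.setdefault(g, set()).add(aa)
        assert by_group == {
            1: set("AGV"),
            2: set("C"),
            3: set("DE"),
            4: set("FILP"),
            5: set("HNQW"),
            6: set("KR"),
            7: set("MSTY"),
        }


class TestAutoCovariance:
    def test_homopolymer_is_zero(self):
        assert np.all(encode_ac("A" * 60) == 0)

    def test_length_is_six_times_lg(self, make_sequence):
        assert encode_ac(make_sequence(100)).shape == (180,)

    def test_toy_sequence_against_double_loop(self):
        seq = "ACDKWV"
        got = encode_ac(seq, lg=2)
        expected = oracles.ac_brute(seq, load_property_table(), 2)
        np.testing.assert_allclose(got, expected, atol=1e-12)

    def test_sequence_too_short(self):
        with pytest.raises(ValueError, match="exceed"):
            encode_ac("ACDEF", lg=5)

    def test_unknown_residue(self):
        with pytest.raises(ValueError, match="'X'"):
            encode_ac("AXCDEF", lg=2)


class TestMoranAutocorrelation:
    def test_homopolymer_zero_by_convention(self):
        assert np.all(encode_mac("W" * 50) == 0)

    def test_length_is_six_times_dmax(self, make_sequence):
        assert encode_mac(make_sequence(100)).shape == (180,)

    def test_toy_sequence_against_double_loop(self):
        seq = "ACDKWVML"
        got = encode_mac(seq, dmax=3)
        expected = oracles.mac_brute(seq, load_property_table(), 3)
        np.testing.assert_allclose(got, expected, atol=1e-12)

    def test_sequence_too_short(self):
        with pytest.raises(ValueError, match="exceed"):
            encode_mac("ACD", dmax=3)


class TestConjointTriad:
    def test_homopolymer_concentrates_on_one_triad(self):
        v = encode_ct("AAAA")
        assert v[0] == 1.0  # triad (1,1,1) at index 0
        assert v.sum() == 1.0 and np.count_nonzero(v) == 1

    def test_length_343(self):
        assert encode_ct("ACDEFGHIKLMW").shape == (343,)

    def test_toy_sequence_against_window_tally(self):
        seq = "ACDKWVMLYRGS"
        np.testing.assert_allclose(
            encode_ct(seq), oracles.ct_brute(seq, load_group_map()), atol=1e-15
        )

    def test_raw_count_mode(self):
        seq = "ACDKWVMLYRGS"
        np.testing.assert_array_equal(
            encode_ct(seq, relative=False),
            oracles.ct_brute(seq, load_group_map(), relative=False),
        )

    def test_too_short(self):
        with pytest.raises(ValueError):
            encode_ct("AC")

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(sequences)
    def test_relative_frequencies_sum_to_one(self, seq):
        v = encode_ct(seq)
        assert np.all(v >= 0)
        assert abs(v.sum() - 1.0) < 1e-12


class TestRegions:
    def test_length_eight_exact_division(self):
        seq = "ACDEFGHI"
        r = split_regions(seq)
        assert [r[k] for k in "ABCD"] == ["AC", "DE", "FG", "HI"]
        assert r["E"] == "ACDE" and r["F"] == "FGHI"
        assert r["G"] == seq[2:6]  # positions 3..6

    def test_length_100_three_quarter_regions(self, make_sequence):
        seq = make_sequence(100)
        r = split_regions(seq)
        assert r["H"] == seq[0:75]  # positions 1-75
        assert r["I"] == seq[25:100]  # positions 26-100
        assert r["J"] == seq[12:87]  # positions 13-87

    def test_too_short(self):
        with pytest.raises(ValueError):
            split_regions("ACD")

    @settings(max_examples=80, derandomize=True, deadline=None)
    @given(sequences)
    def test_quarters_partition_sequence(self, seq):
        r = split_regions(seq)
        assert r["A"] + r["B"] + r["C"] + r["D"] == seq
        assert r["E"] + r["F"] == seq
        assert all(len(r[k]) >= 1 for k in "ABCDEFGHIJ")


class TestCTDRegion:
    def test_homogeneous_region(self):
        v = encode_ctd_region("AAAA")
        assert v[0] == 100.0 and np.all(v[1:7] == 0)  # composition
        assert np.all(v[7:28] == 0)  # transitions
        np.testing.assert_allclose(v[28:33], [25, 25, 50, 75, 100])  # group 1 dist
        assert np.all(v[33:] == 0)

    def test_length_63(self):
        assert encode_ctd_region("ACDKW").shape == (63,)

    def test_against_hand_evaluation(self, make_sequence):
        region = make_sequence(17)
        np.testing.assert_allclose(
            encode_ctd_region(region), oracles.ctd_brute(region, load_group_map()),
            atol=1e-12,
        )

    def test_empty_region_rejected(self):
        with pytest.raises(ValueError):
            encode_ctd_region("")

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(sequences)
    def test_composition_sums_to_100_and_distribution_monotone(self, seq):
        v = encode_ctd_region(seq)
        assert v[:7].sum() == pytest.approx(100.0, abs=1e-9)
        dist = v[28:].reshape(7, 5)
        assert np.all(dist >= 0) and np.all(dist <= 100)
        for row in dist:
            assert np.all(np.diff(row) >= 0)


class TestLocalDescriptors:
    def test_length_630(self, make_sequence):
        assert encode_ld(make_sequence(80)).shape == (630,)

    def test_homopolymer_blocks_match_per_region_patterns(self):
        seq = "A" * 40
        v = encode_ld(seq).reshape(10, 63)
        regions = split_regions(seq)
        for block, name in zip(v, "ABCDEFGHIJ"):
            np.testing.assert_allclose(block, encode_ctd_region(regions[name]))

    def test_length_40_toy_against_per_region_oracle(self, make_sequence):
        seq = make_sequence(40)
        np.testing.assert_allclose(
            encode_ld(seq), oracles.ld_brute(seq, load_group_map()), atol=1e-12
        )


class TestPairVector:
    def test_total_length_2666(self, make_sequence):
        v = encode_pair(make_sequence(100), make_sequence(100))
        assert v.shape == (2666,)
        assert np.all(np.isfinite(v))

    def test_block_layout_widths(self):
        layout = dict(pair_block_layout())
        assert layout == {
            "AC_A": 180, "AC_B": 180, "CT_A": 343, "CT_B": 343,
            "LD_A": 630, "LD_B": 630, "MAC_A": 180, "MAC_B": 180,
        }
        assert sum(layout.values()) == 2666

    def test_blocks_match_individual_encoders(self, make_sequence):
        a, b = make_sequence(90), make_sequence(110)
        v = encode_pair(a, b)
        np.testing.assert_array_equal(v[:180], encode_ac(a))
        np.testing.assert_array_equal(v[180:360], encode_ac(b))
        np.testing.assert_array_equal(v[360:703], encode_ct(a))
        np.testing.assert_array_equal(v[2486:], encode_mac(b))

    def test_swapping_pair_swaps_blocks(self, make_sequence):
        a, b = make_sequence(80), make_sequence(95)
        ab, ba = encode_pair(a, b), encode_pair(b, a)
        # block-wise: A-blocks of (a,b) equal B-blocks of (b,a)
        np.testing.assert_array_equal(ab[:180], ba[180:360])
        np.testing.assert_array_equal(ab[360:703], ba[703:1046])
        np.testing.assert_array_equal(ab[1046:1676], ba[1676:2306])
        np.testing.assert_array_equal(ab[2306:2486], ba[2486:])

    def test_custom_config_changes_width(self, make_sequence):
        cfg = EncoderConfig(lg=10, dmax=5)
        v = encode_pair(make_sequence(60), make_sequence(60), cfg)
        assert v.shape == (2 * (60 + 343 + 630 + 30),)

    def test_pair_encoder_transformer(self, make_sequence):
        pairs = [(make_sequence(70), make_sequence(70)) for _ in range(3)]
        enc = PairEncoder().fit(pairs)
        X = enc.transform(pairs)
        assert X.shape == (3, 2666)
        np.testing.assert_array_equal(X[0], encode_pair(*pairs[0]))
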