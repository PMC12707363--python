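"""Aggregation predictor tracks: window means vs brute force, hot-spot
rules, the hexapeptide pattern, and consensus behaviour."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from splicescout.predictors import (
    aggrescan_track,
    amyloidogenic_pattern_track,
    beta_propensity_track,
    consensus,
    compute_tracks,
    load_scale,
    packing_density_track,
    score_sequence,
    window_mean,
)
from splicescout.records import AMINO_ACIDS, ProteinSequence

seq_strategy = st.text(alphabet=sorted(AMINO_ACIDS), min_size=7, max_size=30)


def brute_window_mean(values, window):
    h = window // 2
    out = []
    for i in range(len(values)):
        lo, hi = max(0, i - h), min(len(values), i + h + 1)
        out.append(sum(values[lo:hi]) / (hi - lo))
    return np.array(out)


@given(seq_strategy, st.sampled_from([3, 5, 7]))
def test_window_mean_matches_brute_force(seq, window):
    scale = load_scale("aggrescan_a3v")
    values = np.array([scale[aa] for aa in seq])
    np.testing.assert_allclose(
        window_mean(values, window), brute_window_mean(values, window), rtol=1e-12
    )


@given(seq_strategy)
def test_window_mean_reversal_symmetry(seq):
    """Symmetric windows: reversing the sequence reverses the track."""
    fwd = aggrescan_track(ProteinSequence("f", seq)).values
    rev = aggrescan_track(ProteinSequence("r", seq[::-1])).values
    np.testing.assert_allclose(fwd, rev[::-1], rtol=1e-12)


class TestAggrescan:
    def test_polyproline_never_hits(self):
        track = aggrescan_track(ProteinSequence("p", "P" * 20))
        assert not track.hits.any()

    def test_polyisoleucine_constant_track_and_full_hotspot(self):
        track = aggrescan_track(ProteinSequence("i", "I" * 10))
        ile = load_scale("aggrescan_a3v")["I"]
        np.testing.assert_allclose(track.values, ile)
        assert track.hits.all()

    def test_short_island_below_min_length_not_called(self):
        # 4 high-propensity residues flanked by strongly negative ones
        seq = ProteinSequence("s", "D" * 8 + "IIII" + "D" * 8)
        track = aggrescan_track(seq, min_hotspot_len=5)
        windowed_positive = (track.values > -0.02).sum()
        assert 0 < windowed_positive < 5  # island exists but is too short
        assert not track.hits.any()

    def test_even_window_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            aggrescan_track(ProteinSequence("x", "A" * 10), window=4)

    def test_window_longer_than_sequence_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            aggrescan_track(ProteinSequence("x", "A" * 4), window=5)


class TestHexapeptidePattern:
    @pytest.mark.parametrize(
        "hexa, matches",
        [
            ("STVIIE", True),   # canonical de novo amyloid hexapeptide
            ("PPPPPP", False),  # P excluded at every informative position
            ("STVIIR", False),  # R excluded at position 6
            ("STVIPE", False),  # P not in the position-5 class [FIY]
            ("SWVIIE", False),  # W excluded at position 2
        ],
    )
    def test_position_classes(self, hexa, matches):
        track = amyloidogenic_pattern_track(ProteinSequence("h", hexa))
        assert track.hits.all() == matches
        assert track.hits.any() == matches

    def test_brute_force_class_check_on_random_windows(self):
        classes = [
            set(AMINO_ACIDS) - set("P"),
            set(AMINO_ACIDS) - set("PKRHW"),
            set("VLSCWFNQE"),
            set("ILTYWFNE"),
            set("FIY"),
            set(AMINO_ACIDS) - set("PKRH"),
        ]
        rng = np.random.default_rng(7)
        letters = sorted(AMINO_ACIDS)
        seq = "".join(rng.choice(letters, size=30))
        track = amyloidogenic_pattern_track(ProteinSequence("r", seq))
        expected = np.zeros(30, dtype=bool)
        for i in range(25):
            if all(seq[i + j] in classes[j] for j in range(6)):
                expected[i : i + 6] = True
        np.testing.assert_array_equal(track.hits, expected)

    def test_short_sequence_gives_all_false(self):
        track = amyloidogenic_pattern_track(ProteinSequence("s", "STVII"))
        assert len(track) == 5 and not track.hits.any()


class TestScaleTracks:
    def test_constant_sequence_constant_packing_track(self):
        track = packing_density_track(ProteinSequence("a", "A" * 12))
        np.testing.assert_allclose(track.values, load_scale("packing_density")["A"])

    def test_infinite_threshold_no_hits(self):
        track = packing_density_track(
            ProteinSequence("i", "I" * 12), threshold=np.inf
        )
        assert not track.hits.any()

    def test_alternating_residues_window_means_positionally(self):
        seq = "IDIDIDIDID"  # alternating high/low packing density
        track = packing_density_track(ProteinSequence("x", seq), window=5)
        scale = load_scale("packing_density")
        values = [scale[aa] for aa in seq]
        np.testing.assert_allclose(track.values, brute_window_mean(values, 5))

    def test_poly_v_beta_track_exceeds_poly_g(self):
        v = beta_propensity_track(ProteinSequence("v", "V" * 10)).values
        g = beta_propensity_track(ProteinSequence("g", "G" * 10)).values
        assert (v > g).all()

    def test_degenerate_window_center_equals_global_mean(self):
        # window = sequence length: the central position sees every residue;
        # terminal positions average over the truncated window
        seq = ProteinSequence("m", "AVLDKGQW" + "A")
        track = beta_propensity_track(seq, window=len(seq))
        scale = load_scale("beta_propensity")
        values = [scale[aa] for aa in seq.residues]
        assert track.values[len(seq) // 2] == pytest.approx(np.mean(values))
        np.testing.assert_allclose(track.values, brute_window_mean(values, len(seq)))

    def test_threshold_above_scale_max_no_beta_hits(self):
        track = beta_propensity_track(ProteinSequence("v", "V" * 12), threshold=2.0)
        assert not track.hits.any()


class TestConsensus:
    def test_majority_counting(self):
        tracks = compute_tracks(ProteinSequence("x", "S" * 8 + "STVIIE" + "S" * 8))
        cons = consensus(tracks, threshold=2)
        assert cons.counts.max() >= 2
        np.testing.assert_array_equal(cons.hits, cons.counts >= 2)

    @given(
        st.lists(
            st.lists(st.booleans(), min_size=12, max_size=12),
            min_size=2,
            max_size=5,
        )
    )
    def test_threshold_one_is_or_and_threshold_n_is_and(self, masks):
        from splicescout.predictors import ResidueTrack

        tracks = [
            ResidueTrack(f"m{i}", np.zeros(12), np.array(m))
            for i, m in enumerate(masks)
        ]
        union = consensus(tracks, threshold=1).hits
        inter = consensus(tracks, threshold=len(tracks)).hits
        np.testing.assert_array_equal(union, np.logical_or.reduce([t.hits for t in tracks]))
        np.testing.assert_array_equal(inter, np.logical_and.reduce([t.hits for t in tracks]))

    @given(
        st.lists(
            st.lists(st.booleans(), min_size=10, max_size=10),
            min_size=3,
            max_size=5,
        )
    )
    def test_monotone_in_threshold(self, masks):
        """Raising the consensus threshold never adds hits."""
        from splicescout.predictors import ResidueTrack

        tracks = [
            ResidueTrack(f"m{i}", np.zeros(10), np.array(m))
            for i, m in enumerate(masks)
        ]
        previous = None
        for thr in range(1, len(tracks) + 1):
            hits = consensus(tracks, threshold=thr).hits
            if previous is not None:
                assert not (hits & ~previous).any()
            previous = hits

    def test_unanimity_with_dissent_gives_no_hit(self):
        from splicescout.predictors import ResidueTrack

        agree = ResidueTrack("a", np.zeros(6), np.ones(6, dtype=bool))
        dissent = ResidueTrack("d", np.zeros(6), np.zeros(6, dtype=bool))
        cons = consensus([agree, agree, dissent], threshold=3)
        assert not cons.hits.any()

    def test_mixed_lengths_rejected(self):
        from splicescout.predictors import ResidueTrack

        a = ResidueTrack("a", np.zeros(5), np.zeros(5, dtype=bool))
        b = ResidueTrack("b", np.zeros(6), np.zeros(6, dtype=bool))
        with pytest.raises(ValueError, match="mixed lengths"):
            consensus([a, b])

    def test_empty_track_list_rejected(self):
        with pytest.raises(ValueError, match="no tracks"):
            consensus([])

    @pytest.mark.parametrize("threshold", [1, 2])
    def test_stviie_insertion_increases_consensus_hits(self, threshold):
        """The amyloid hexapeptide fires both the pattern and the
        beta-propensity methods, so consensus hits strictly increase."""
        plain = score_sequence(
            ProteinSequence("p", "S" * 40), consensus_threshold=threshold
        )
        inserted = score_sequence(
            ProteinSequence("i", "S" * 17 + "STVIIE" + "S" * 17),
            consensus_threshold=threshold,
        )
        assert inserted.hits.sum() > plain.hits.sum()
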