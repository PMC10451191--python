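"""Class statistics and inverse-frequency rebalancing weights."""

from fractions import Fraction

import numpy as np
import pytest

from tailseg.errors import DataError
from tailseg.synthetic import SyntheticConfig, generate_dataset
from tailseg.weights import (ClassStats, compute_class_stats,
                             image_based_weights, pixel_based_weights,
                             read_class_stats, uniform_weights,
                             write_class_stats, write_weights)

from _oracles import class_stats_loop
from conftest import make_labeled

STUDY_IMAGE_COUNTS = (1603, 869, 1090, 201)
STUDY_PIXEL_COUNTS = (13_501_701, 659_031, 10_655_977, 39_608)


def stats_from_counts(image_counts, pixel_counts=None):
    C = len(image_counts)
    if pixel_counts is None:
        pixel_counts = image_counts
    return ClassStats(tuple(range(1, C + 1)), tuple(image_counts),
                      tuple(pixel_counts))


class TestComputeClassStats:
    def test_empty_dataset(self):
        stats = compute_class_stats([], 4)
        assert stats.image_counts == (0, 0, 0, 0)
        assert stats.pixel_counts == (0, 0, 0, 0)

    def test_hand_countable_mask(self):
        stats = compute_class_stats([make_labeled([[0, 1], [1, 4]])], 4)
        assert stats.image_counts == (1, 0, 0, 1)
        assert stats.pixel_counts == (2, 0, 0, 1)

    def test_matches_pixel_loop_oracle_on_synthetic_masks(self):
        cfg = SyntheticConfig(n_images=50, image_size=32,
                              radius_range=((4, 8), (2, 4), (2, 5), (1, 2)),
                              seed=7)
        dataset, _ = generate_dataset(cfg)
        stats = compute_class_stats(dataset, 4)
        img, pix = class_stats_loop([d.mask for d in dataset], 4)
        assert stats.image_counts == tuple(img)
        assert stats.pixel_counts == tuple(pix)

    def test_out_of_range_label_names_offender(self):
        ds = [make_labeled([[0, 7]], "badfile")]
        with pytest.raises(DataError, match="badfile"):
            compute_class_stats(ds, 4)


class TestImageBasedWeights:
    def test_study_counts_reproduce_printed_row(self):
        wv = image_based_weights(stats_from_counts(STUDY_IMAGE_COUNTS),
                                 mode="sum_to_one")
        assert tuple(round(w, 3) for w in wv.weights) == (0.081, 0.150, 0.120, 0.649)

    def test_equal_counts_give_unit_weights(self):
        wv = image_based_weights(stats_from_counts((10, 10, 10, 10)), mode="eq6")
        assert np.allclose(wv.weights, 1.0)

    def test_eq6_equals_exact_rational_evaluation(self):
        counts = STUDY_IMAGE_COUNTS
        C = len(counts)
        inv_sum = sum(Fraction(1, n) for n in counts)
        exact = [Fraction(C, 1) / (n * inv_sum) for n in counts]
        wv = image_based_weights(stats_from_counts(counts), mode="eq6")
        sto = image_based_weights(stats_from_counts(counts), mode="sum_to_one")
        assert np.allclose(wv.weights, [float(e) for e in exact], atol=1e-12)
        assert np.allclose(wv.weights, 4 * np.array(sto.weights), atol=1e-12)

    def test_absent_class_is_a_hard_error(self):
        with pytest.raises(DataError, match="exclude|floor"):
            image_based_weights(stats_from_counts((5, 0, 3, 1)))

    def test_proportions_are_inverse_ratios(self):
        counts = (2, 4)
        wv = image_based_weights(stats_from_counts(counts))
        assert wv.proportions == (3.0, 1.5)  # sum(counts)/count


class TestPixelBasedWeights:
    def test_study_counts_reproduce_printed_row_approximately(self):
        stats = stats_from_counts((1, 1, 1, 1), STUDY_PIXEL_COUNTS)
        wv = pixel_based_weights(stats, mode="sum_to_one")
        printed = (0.0027, 0.0564, 0.0034, 0.9375)
        assert np.allclose(wv.weights, printed, atol=1e-3)

    def test_equal_pixel_counts_give_uniform_share(self):
        stats = stats_from_counts((1, 1, 1, 1), (500, 500, 500, 500))
        wv = pixel_based_weights(stats, mode="sum_to_one")
        assert np.allclose(wv.weights, 0.25)

    def test_two_class_hand_evaluation(self):
        stats = stats_from_counts((1, 1), (3, 1))
        wv = pixel_based_weights(stats, mode="eq6")
        assert np.allclose(wv.weights, (0.5, 1.5), atol=1e-12)

    def test_zero_pixel_count_errors(self):
        stats = stats_from_counts((1, 1), (3, 0))
        with pytest.raises(DataError):
            pixel_based_weights(stats)


class TestWeightInvariants:
    """Fuzzed invariants over random positive integer count vectors."""

    def _random_counts(self, rng):
        C = int(rng.integers(2, 8))
        return rng.integers(1, 10_000, size=C)

    def test_normalisation_antimonotonicity_and_scale_invariance(self):
        rng = np.random.default_rng(99)
        for _ in range(1000):
            counts = self._random_counts(rng)
            C = len(counts)
            stats = stats_from_counts(tuple(counts))
            eq6 = image_based_weights(stats, mode="eq6")
            sto = image_based_weights(stats, mode="sum_to_one")
            assert abs(sum(eq6.weights) - C) < 1e-9
            assert abs(sum(sto.weights) - 1.0) < 1e-9
            w = np.array(eq6.weights)
            # strict anti-monotonicity in the counts
            for i in range(C):
                for j in range(C):
                    if counts[i] < counts[j]:
                        assert w[i] > w[j]
            # scale invariance
            k = int(rng.integers(2, 50))
            scaled = image_based_weights(stats_from_counts(tuple(counts * k)),
                                         mode="eq6")
            assert np.allclose(scaled.weights, eq6.weights, atol=1e-9)
            # mode relationship
            assert np.allclose(np.array(sto.weights) * C, w, atol=1e-9)


class TestUniformWeights:
    def test_unit_weights_and_background(self):
        wv = uniform_weights(4, background_weight=2.0)
        assert wv.weights == (1.0,) * 4
        assert np.array_equal(wv.full_weights(), [2.0, 1, 1, 1, 1])


class TestStatsIO:
    def test_round_trip(self, tmp_path):
        stats = stats_from_counts(STUDY_IMAGE_COUNTS, STUDY_PIXEL_COUNTS)
        path = tmp_path / "stats.txt"
        write_class_stats(stats, path)
        assert read_class_stats(path) == stats

    def test_weight_file_records_mode(self, tmp_path):
        wv = image_based_weights(stats_from_counts(STUDY_IMAGE_COUNTS))
        path = tmp_path / "w.txt"
        write_weights(wv, path)
        text = path.read_text()
        assert "mode=eq6" in text and "background_weight=1.0" in text

    def test_malformed_header_rejected(self, tmp_path):
        path = tmp_path / "bad.txt"
        path.write_text("nope\n1,2,3\n")
        with pytest.raises(DataError):
            read_class_stats(path)
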