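import itertools

import numpy as np
import pytest
from hypothesis import given, strategies as st
from hypothesis.extra import numpy as hnp

from eulerquad import (
    BinaryImage,
    BitQuad,
    access_model,
    beside,
    classify_bitquad,
    euler_oracle,
    euler_two_pattern,
    pattern_index,
    scan_two_pattern,
)

from conftest import img, random_images

ALL_QUADS = [BitQuad(*bits) for bits in itertools.product((0, 1), repeat=4)]

grids = hnp.arrays(
    np.uint8,
    st.tuples(st.integers(0, 10), st.integers(0, 10)),
    elements=st.integers(0, 1),
)


class TestClassify:
    def test_q2_is_isolated_representative(self):
        assert classify_bitquad(BitQuad(u=0, v=0, x=0, y=1)) == (True, False)

    @pytest.mark.parametrize("y", [0, 1])
    def test_qc_ignores_representative(self, y):
        assert classify_bitquad(BitQuad(u=0, v=1, x=1, y=y)) == (False, True)

    def test_object_corner_excludes_both(self):
        for q in ALL_QUADS:
            if q.u == 1:
                assert classify_bitquad(q) == (False, False)

    def test_flags_mutually_exclusive(self):
        for q in ALL_QUADS:
            assert classify_bitquad(q) != (True, True)


class TestPatternIndex:
    def test_bijection(self):
        assert sorted(pattern_index(q) for q in ALL_QUADS) == list(range(1, 17))

    def test_class_partition(self):
        """U=1 -> Q9-Q16; U=0,X=1 -> Q5-Q8; U=0,X=0 -> Q1-Q4."""
        for q in ALL_QUADS:
            idx = pattern_index(q)
            if q.u == 1:
                assert 9 <= idx <= 16
            elif q.x == 1:
                assert 5 <= idx <= 8
            else:
                assert 1 <= idx <= 4

    def test_named_patterns(self):
        assert pattern_index(BitQuad(0, 0, 0, 1)) == 2  # Q2
        assert {pattern_index(BitQuad(0, 1, 1, y)) for y in (0, 1)} == {7, 8}  # Qc


class TestScan:
    def test_empty_image(self):
        c = scan_two_pattern(BinaryImage(np.zeros((0, 0), np.uint8)))
        assert (c.w2, c.wc) == (0, 0)

    def test_single_pixel(self):
        c = scan_two_pattern(BinaryImage([[1]]))
        assert (c.w2, c.wc) == (1, 0)
        assert c.euler == 1

    def test_ring_counts(self, ring3):
        # hand enumeration of the sixteen windows of the padded ring:
        # one isolated-corner Q2 at the top-left, one Qc at the hole
        c = scan_two_pattern(ring3)
        assert (c.w2, c.wc) == (1, 1)
        assert c.euler == 0

    def test_two_isolated_pixels(self):
        image = img([[1, 0, 0, 1]])
        assert euler_two_pattern(image) == 2 == euler_oracle(image)

    def test_invalid_group(self, ring3):
        with pytest.raises(ValueError):
            scan_two_pattern(ring3, group="z")

    def test_bitquads_accounting(self, ring3):
        c = scan_two_pattern(ring3)
        windows = (ring3.height + 1) * (ring3.width + 1)
        assert c.bitquads_processed + c.skipped == windows

    @given(grids)
    def test_read_bounds(self, grid):
        """Reads per processed bit-quad stay within [1, 4]."""
        c = scan_two_pattern(BinaryImage(grid))
        assert c.bitquads_processed <= c.reads <= 4 * c.bitquads_processed

    def test_all_foreground_interior_costs_one_read(self):
        """Once U is a real foreground pixel the window costs one read."""
        image = img(np.ones((6, 6), np.uint8))
        c = scan_two_pattern(image)
        # first window row: 4 fresh reads then 2 carried reads per window;
        # each later row: 3 reads at the row start (U, V, X with X=1),
        # one skipped window, then 1 read (U=1) for each remaining window
        assert c.skipped == 6
        assert c.reads == (4 + 2 * 6) + 6 * (3 + 5)
        assert c.euler == 1

    @given(grids, st.sampled_from("abcd"))
    def test_groups_agree(self, grid, group):
        image = BinaryImage(grid)
        assert euler_two_pattern(image, group) == euler_two_pattern(image, "a")

    @given(grids, st.integers(1, 3))
    def test_rotation_invariance(self, grid, k):
        image = BinaryImage(grid)
        assert euler_two_pattern(image.rotate90(k)) == euler_two_pattern(image)

    @given(grids, st.integers(1, 3))
    def test_padding_invariance(self, grid, margin):
        image = BinaryImage(grid)
        assert euler_two_pattern(image.padded(margin)) == euler_two_pattern(image)

    @given(grids, grids)
    def test_additivity_of_disjoint_composites(self, left, right):
        a, b = BinaryImage(left), BinaryImage(right)
        assert euler_two_pattern(beside(a, b)) == euler_two_pattern(
            a
        ) + euler_two_pattern(b)

    def test_matches_oracle_on_random_images(self):
        for image, _ in random_images(count=60, max_side=24, seed=11):
            assert euler_two_pattern(image) == euler_oracle(image)


class TestAccessModel:
    def test_class_sizes(self):
        model = access_model()
        sizes = {
            cls: sum(1 for c in model.class_of_pattern.values() if c == cls)
            for cls in ("R1", "R2", "R3")
        }
        assert sizes == {"R1": 8, "R2": 4, "R3": 4}

    def test_object_corner_class_costs_one_read(self):
        model = access_model()
        for q in ALL_QUADS:
            if q.u == 1:
                cls = model.class_of_pattern[pattern_index(q)]
                assert cls == "R1"
        assert model.expected_reads["R1"] == 1.0

    def test_r3_follow_probability(self):
        assert access_model().prob_r3_after_r3 == 0.25

    def test_expected_reads(self):
        model = access_model()
        assert model.expected_reads["R2"] == 1.5
        assert model.expected_reads["R3"] == 3.5
        assert model.average == 1.75

    def test_average_consistent_with_classes(self):
        model = access_model()
        total = sum(
            model.expected_reads[model.class_of_pattern[q]] for q in range(1, 17)
        )
        assert model.average == total / 16
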