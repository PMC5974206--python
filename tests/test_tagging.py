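import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from scipy import ndimage

from punctakit.tagging import (
    bhattacharyya,
    connect_slices,
    measure,
    size_check,
    slice_tagging,
)

# in-plane 8-connectivity plus pure-z neighbours: the connectivity realized by
# per-slice tagging followed by overlap-based slice connection
PLANAR8_Z_STRUCTURE = np.zeros((3, 3, 3), bool)
PLANAR8_Z_STRUCTURE[1] = True
PLANAR8_Z_STRUCTURE[0, 1, 1] = PLANAR8_Z_STRUCTURE[2, 1, 1] = True


def partitions_equal(a: np.ndarray, b: np.ndarray) -> bool:
    """True when two labelings induce the same partition of the foreground."""
    if ((a > 0) != (b > 0)).any():
        return False
    pairs = set(zip(a.ravel().tolist(), b.ravel().tolist()))
    return len(pairs) == len(np.unique(a)) == len(np.unique(b))


class TestSliceTagging:
    def test_uniform_blob_is_single_object(self):
        img = np.zeros((5, 5))
        img[1:4, 1:4] = 7.0
        labels = slice_tagging(img, toll=0.0)
        assert set(np.unique(labels)) == {0, 1}
        assert (labels[1:4, 1:4] == 1).all()

    def test_two_peaks_with_lower_valley_split(self):
        img = np.array(
            [
                [0, 0, 0, 0, 0],
                [0, 5, 3, 5, 0],
                [0, 0, 0, 0, 0],
            ],
            dtype=float,
        )
        labels = slice_tagging(img, toll=0.0)
        assert labels.max() == 2
        assert labels[1, 1] != labels[1, 3]
        # the valley pixel joins one of the peaks and everything is tagged
        assert (labels[img > 0] > 0).all()

    def test_toll_above_range_merges_the_valley(self):
        img = np.array([[0, 0, 0, 0, 0], [0, 5, 3, 5, 0]], dtype=float)
        assert slice_tagging(img, toll=10.0).max() == 1

    @pytest.mark.parametrize("seed", range(10))
    def test_large_toll_equals_connected_components(self, seed):
        rng = np.random.default_rng(seed)
        img = np.where(rng.random((24, 24)) < 0.4, rng.integers(1, 256, (24, 24)), 0)
        mine = slice_tagging(img.astype(float), toll=np.inf)
        ref, _ = ndimage.label(img > 0, structure=np.ones((3, 3), bool))
        assert partitions_equal(mine, ref)

    def test_empty_foreground(self):
        assert slice_tagging(np.zeros((4, 4))).max() == 0

    def test_four_connectivity_separates_diagonals(self):
        img = np.array([[5, 0], [0, 5]], dtype=float)
        assert slice_tagging(img, 0.0, connectivity=8).max() == 1
        assert slice_tagging(img, 0.0, connectivity=4).max() == 2

    @given(
        img=arrays(
            np.int64, (12, 12), elements=st.integers(0, 40)
        ),
        toll=st.floats(0, 50),
    )
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_every_foreground_pixel_tagged_exactly_once(self, img, toll):
        labels = slice_tagging(img.astype(float), toll)
        assert ((labels > 0) == (img > 0)).all()


class TestBhattacharyya:
    def test_identical_distributions_give_one(self):
        obj = {(0, 0): 3.0, (1, 0): 5.0, (1, 1): 2.0}
        assert bhattacharyya(obj, dict(obj)) == pytest.approx(1.0)

    def test_disjoint_supports_give_zero(self):
        assert bhattacharyya({(0, 0): 2.0}, {(5, 5): 2.0}) == 0.0

    def test_hand_computed_partial_overlap(self):
        obj_i = {(0, 0): 2.0, (1, 0): 2.0}
        obj_j = {(1, 0): 3.0, (2, 0): 1.0}
        assert bhattacharyya(obj_i, obj_j) == pytest.approx(
            np.sqrt(0.5 * 0.75), abs=1e-4
        )

    def test_zero_intensity_object_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            bhattacharyya({(0, 0): 0.0}, {(0, 0): 1.0})

    @given(
        st.dictionaries(
            st.tuples(st.integers(0, 3), st.integers(0, 3)),
            st.floats(0.1, 50),
            min_size=1,
            max_size=10,
        ),
        st.dictionaries(
            st.tuples(st.integers(0, 3), st.integers(0, 3)),
            st.floats(0.1, 50),
            min_size=1,
            max_size=10,
        ),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_bounded_and_symmetric(self, a, b):
        bc = bhattacharyya(a, b)
        assert 0.0 <= bc <= 1.0
        assert bc == pytest.approx(bhattacharyya(b, a))


class TestConnectSlices:
    def _stack_from_slices(self, slices):
        fused = np.stack([np.asarray(s, float) for s in slices])
        labels = [slice_tagging(fused[z], 0.0) for z in range(len(slices))]
        return labels, fused

    def test_identical_object_on_three_slices_is_one_object(self):
        sl = np.zeros((6, 6))
        sl[2:4, 2:4] = 9.0
        labels, fused = self._stack_from_slices([sl, sl, sl])
        out = connect_slices(labels, fused, phi=0.4)
        assert out.max() == 1
        assert (out[fused > 0] == 1).all()

    def test_phi_one_never_joins(self):
        sl = np.zeros((6, 6))
        sl[2:4, 2:4] = 9.0
        labels, fused = self._stack_from_slices([sl, sl, sl])
        out = connect_slices(labels, fused, phi=1.0)
        assert out.max() == 3  # one object per slice

    def test_transitive_chain_merges_all_three(self):
        """A joins B and B joins C across adjacent slices; A and C end up in
        the same 3D object even though they are not adjacent."""
        a = np.zeros((6, 6)); a[2:4, 2:4] = 9.0
        b = np.zeros((6, 6)); b[2:4, 2:4] = 9.0
        c = np.zeros((6, 6)); c[2:4, 2:4] = 9.0
        labels, fused = self._stack_from_slices([a, b, c])
        out = connect_slices(labels, fused, phi=0.9)
        assert out.max() == 1

    def test_tag_conservation(self, rng):
        fused = np.where(rng.random((4, 16, 16)) < 0.3, rng.random((4, 16, 16)) * 99, 0)
        labels = [slice_tagging(fused[z], 0.0) for z in range(4)]
        out = connect_slices(labels, fused, phi=0.4)
        assert ((out > 0) == (fused > 0)).all()

    @pytest.mark.parametrize("seed", range(50))
    def test_inf_toll_zero_phi_equals_3d_components(self, seed):
        """With toll = inf and phi = 0 the whole labeler reduces to standard
        connected-component labeling (in-plane 8-connectivity, slices linked
        through vertically overlapping pixels)."""
        rng = np.random.default_rng(1000 + seed)
        shape = (4, 16, 16)
        fused = np.where(
            rng.random(shape) < 0.35, rng.integers(1, 256, shape).astype(float), 0.0
        )
        labels = [slice_tagging(fused[z], np.inf) for z in range(shape[0])]
        mine = connect_slices(labels, fused, phi=0.0)
        ref, _ = ndimage.label(fused > 0, structure=PLANAR8_Z_STRUCTURE)
        assert ((mine > 0) == (ref > 0)).all()
        pairs = set(zip(mine.ravel().tolist(), ref.ravel().tolist()))
        assert len(pairs) == len(np.unique(mine)) == len(np.unique(ref))


class TestSizeCheck:
    def test_zero_min_size_is_identity(self, rng):
        labels = rng.integers(0, 4, (3, 8, 8))
        np.testing.assert_array_equal(size_check(labels, 0), labels)

    def test_isolated_small_object_removed(self):
        labels = np.zeros((3, 8, 8), dtype=np.int32)
        labels[1, 2:4, 2:4] = 1  # 4 voxels, nothing adjacent
        out = size_check(labels, min_size=40)
        assert out.max() == 0

    def test_small_object_merges_into_touching_neighbour(self):
        labels = np.zeros((3, 10, 10), dtype=np.int32)
        labels[:, 2:8, 2:6] = 1  # 72 voxels
        labels[1, 4:6, 6:8] = 2  # 4 voxels touching object 1
        before = (labels > 0).sum()
        out = size_check(labels, min_size=40)
        assert set(np.unique(out)) == {0, 1}
        assert (out > 0).sum() == before  # merged, not deleted

    def test_never_increases_object_count_nor_foreground(self, rng):
        fused = np.where(rng.random((4, 20, 20)) < 0.3, rng.random((4, 20, 20)), 0)
        labels = [slice_tagging(fused[z], 0.0) for z in range(4)]
        joined = connect_slices(labels, fused, 0.4)
        out = size_check(joined, min_size=5)
        assert len(np.unique(out)) <= len(np.unique(joined))
        assert (out > 0).sum() <= (joined > 0).sum()


class TestMeasure:
    def test_single_voxel_unit_cube(self):
        labels = np.zeros((8, 8, 8), dtype=np.int32)
        labels[5, 5, 5] = 1
        (rec,) = measure(labels, pixel_size_xy=1.0, z_step=1.0)
        assert rec.centroid_px == (5.0, 5.0, 5.0)
        assert rec.volume_um3 == 1.0
        assert rec.surface_um2 == 6.0
        assert not rec.touches_exclusion

    def test_2x2x2_cube_geometry(self):
        labels = np.zeros((4, 4, 4), dtype=np.int32)
        labels[1:3, 1:3, 1:3] = 1
        (rec,) = measure(labels)
        assert rec.volume_vox == 8
        assert rec.surface_um2 == 24.0

    def test_anisotropic_calibration(self):
        labels = np.zeros((3, 3, 3), dtype=np.int32)
        labels[1, 1, 1] = 1
        (rec,) = measure(labels, pixel_size_xy=0.1, z_step=0.14)
        assert rec.volume_um3 == pytest.approx(0.1 * 0.1 * 0.14)
        # 2 z-normal faces of px^2 + 4 side faces of px*z_step
        assert rec.surface_um2 == pytest.approx(2 * 0.01 + 4 * 0.1 * 0.14)
        assert rec.centroid_um == pytest.approx((0.1, 0.1, 0.14))

    def test_exclusion_faces(self):
        labels = np.zeros((4, 4, 4), dtype=np.int32)
        labels[2, 2, 0] = 1  # on the x = 0 face
        labels[2, 2, 3] = 2  # on the x = max face (an inclusion border)
        recs = {r.tag: r for r in measure(labels)}
        assert recs[1].touches_exclusion
        assert not recs[2].touches_exclusion
        recs = {r.tag: r for r in measure(labels, exclusion_faces=("x1", "y1", "z1"))}
        assert not recs[1].touches_exclusion
        assert recs[2].touches_exclusion

    def test_shared_face_counted_for_both_objects(self):
        labels = np.zeros((1, 1, 2), dtype=np.int32)
        labels[0, 0, 0], labels[0, 0, 1] = 1, 2
        recs = {r.tag: r for r in measure(labels)}
        assert recs[1].surface_um2 == 6.0
        assert recs[2].surface_um2 == 6.0
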