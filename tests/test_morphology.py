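import numpy as np
import pytest

from aucseg import connected_components, dilate, fill_holes, largest_component
from aucseg.io_model import AucsegError
from aucseg.morphology import default_kernel

from _oracles import fill_holes_bruteforce, flood_fill_components


def _canonical(labels):
    """Relabel components by order of first raster-scan appearance."""
    flat = labels.ravel()
    order = {}
    out = np.zeros_like(flat)
    for i, v in enumerate(flat):
        if v:
            out[i] = order.setdefault(v, len(order) + 1)
    return out.reshape(labels.shape)


class TestConnectedComponents:
    @pytest.mark.parametrize("connectivity", [6, 18, 26])
    @pytest.mark.parametrize("seed", range(12))
    def test_agrees_with_flood_fill_oracle(self, connectivity, seed):
        rng = np.random.default_rng(seed)
        mask = rng.uniform(size=(10, 10, 10)) < 0.35
        labeling = connected_components(mask, connectivity)
        oracle_labels, oracle_count = flood_fill_components(mask, connectivity)
        assert labeling.count == oracle_count
        np.testing.assert_array_equal(
            _canonical(labeling.labels), _canonical(oracle_labels)
        )
        assert labeling.sizes.sum() == mask.sum()

    def test_two_isolated_voxels(self):
        mask = np.zeros((5, 5, 5), dtype=bool)
        mask[0, 0, 0] = mask[4, 4, 4] = True
        assert connected_components(mask, 26).count == 2

    @pytest.mark.parametrize("connectivity,expected", [(6, 2), (18, 2), (26, 1)])
    def test_corner_touching_voxels(self, connectivity, expected):
        mask = np.zeros((3, 3, 3), dtype=bool)
        mask[0, 0, 0] = mask[1, 1, 1] = True
        assert connected_components(mask, connectivity).count == expected

    def test_empty_mask(self):
        labeling = connected_components(np.zeros((4, 4, 4), dtype=bool), 26)
        assert labeling.count == 0
        assert not labeling.labels.any()

    def test_invalid_connectivity_rejected(self):
        with pytest.raises(AucsegError, match="connectivity"):
            connected_components(np.ones((2, 2, 2), dtype=bool), 10)


class TestLargestComponent:
    def test_keeps_biggest(self):
        mask = np.zeros((10, 10, 10), dtype=bool)
        mask[1:6, 1:6, 1:5] = True  # 100 voxels
        mask[8, 8, 6:9] = True  # 3 voxels
        out = largest_component(mask)
        assert out.sum() == 100
        assert not out[8, 8, 6]

    def test_single_component_identity(self):
        mask = np.zeros((5, 5, 5), dtype=bool)
        mask[1:4, 1:4, 1:4] = True
        np.testing.assert_array_equal(largest_component(mask), mask)

    def test_tie_broken_toward_smaller_min_linear_index(self):
        mask = np.zeros((5, 5, 5), dtype=bool)
        mask[0, 0, 0:2] = True
        mask[4, 4, 2:4] = True
        out = largest_component(mask)
        assert out[0, 0, 0] and not out[4, 4, 2]

    def test_empty_input_warns(self):
        with pytest.warns(UserWarning, match="empty"):
            out = largest_component(np.zeros((3, 3, 3), dtype=bool))
        assert not out.any()


class TestFillHoles:
    def test_hollow_shell_becomes_solid_cube(self):
        mask = np.zeros((5, 5, 5), dtype=bool)
        mask[1:4, 1:4, 1:4] = True
        mask[2, 2, 2] = False  # 26-voxel shell
        filled = fill_holes(mask)
        assert filled.sum() == 27
        assert filled[2, 2, 2]

    def test_solid_blob_unchanged(self):
        mask = np.zeros((6, 6, 6), dtype=bool)
        mask[2:5, 2:5, 2:5] = True
        np.testing.assert_array_equal(fill_holes(mask), mask)

    def test_border_open_cavity_unchanged(self):
        # C-shaped blob: cavity tunnels to the volume border
        mask = np.zeros((5, 5, 5), dtype=bool)
        mask[1:4, 1:4, 1:4] = True
        mask[2, 2, :] = False  # tunnel along x through both faces of the blob
        np.testing.assert_array_equal(fill_holes(mask), mask)

    @pytest.mark.parametrize("seed", range(8))
    @pytest.mark.parametrize("bg_connectivity", [6, 26])
    def test_matches_bruteforce_and_is_idempotent(self, seed, bg_connectivity):
        rng = np.random.default_rng(seed)
        mask = rng.uniform(size=(9, 9, 9)) < 0.5
        filled = fill_holes(mask, bg_connectivity)
        np.testing.assert_array_equal(
            filled, fill_holes_bruteforce(mask, bg_connectivity)
        )
        np.testing.assert_array_equal(fill_holes(filled, bg_connectivity), filled)
        assert np.all(filled >= mask)  # output superset of input


class TestDilate:
    def test_single_voxel_default_kernel_yields_27(self):
        mask = np.zeros((7, 7, 7), dtype=bool)
        mask[3, 3, 3] = True
        assert dilate(mask).sum() == 27

    def test_empty_mask_stays_empty(self):
        assert not dilate(np.zeros((4, 4, 4), dtype=bool)).any()

    def test_trivial_kernel_is_identity_on_grayscale(self):
        rng = np.random.default_rng(0)
        vol = rng.uniform(size=(5, 5, 5))
        np.testing.assert_allclose(dilate(vol, np.ones((1, 1, 1), dtype=bool)), vol)

    def test_kernel_truncated_at_border(self):
        mask = np.zeros((5, 5, 5), dtype=bool)
        mask[0, 0, 0] = True
        assert dilate(mask).sum() == 8  # corner voxel: only the in-volume octant

    def test_extensive_and_monotone_on_binary_masks(self):
        rng = np.random.default_rng(2)
        small = rng.uniform(size=(8, 8, 8)) < 0.2
        big = small | (rng.uniform(size=small.shape) < 0.2)
        d_small, d_big = dilate(small), dilate(big)
        assert np.all(d_small >= small)  # extensive
        assert np.all(d_big >= d_small)  # increasing in the input

    def test_grayscale_is_local_maximum(self):
        vol = np.zeros((3, 3, 3))
        vol[1, 1, 1] = 5.0
        out = dilate(vol)
        assert np.all(out == 5.0)

    @pytest.mark.parametrize(
        "kernel",
        [np.ones((2, 3, 3), dtype=bool), np.zeros((3, 3, 3), dtype=bool)],
        ids=["even-extent", "center-false"],
    )
    def test_invalid_kernels_rejected(self, kernel):
        with pytest.raises(AucsegError):
            dilate(np.zeros((4, 4, 4), dtype=bool), kernel)

    def test_default_kernel_shape(self):
        k = default_kernel()
        assert k.shape == (3, 3, 3) and k.all()
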