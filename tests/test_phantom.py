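"""Phantom generation, mask morphology and derived planning structures."""

import numpy as np
import pytest

import lexiplan as lp
from lexiplan.phantom import (GridSpec, PhantomParams, expand_mask,
                              hull_fill_fraction, shell_at, skin_ring)


def brute_force_expand(mask, margin, vox):
    """Independent O(N^2) Euclidean expansion over voxel centers."""
    pts = np.argwhere(mask) * np.asarray(vox)
    out = np.zeros_like(mask)
    for idx in np.ndindex(mask.shape):
        c = np.asarray(idx) * np.asarray(vox)
        if pts.size and np.min(np.linalg.norm(pts - c, axis=1)) <= margin:
            out[idx] = True
    return out


class TestExpandMask:
    def test_zero_margin_is_identity(self):
        rng = np.random.default_rng(0)
        mask = rng.random((6, 6, 6)) > 0.7
        assert np.array_equal(expand_mask(mask, 0.0), mask)

    def test_empty_mask_stays_empty(self):
        assert not expand_mask(np.zeros((5, 5, 5), bool), 10.0).any()

    def test_single_voxel_face_neighbors(self):
        # 2 mm isotropic grid, 2 mm margin: the voxel plus its 6 face
        # neighbors (diagonals are at 2*sqrt(2) mm)
        mask = np.zeros((5, 5, 5), bool)
        mask[2, 2, 2] = True
        out = expand_mask(mask, 2.0, (2.0, 2.0, 2.0))
        assert out.sum() == 7
        assert out[2, 2, 2] and out[1, 2, 2] and out[2, 1, 2] and out[2, 2, 3]

    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        mask = rng.random((7, 6, 5)) > 0.85
        vox = (1.5, 2.0, 2.5)
        got = expand_mask(mask, 3.1, vox)
        assert np.array_equal(got, brute_force_expand(mask, 3.1, vox))

    def test_monotone_in_margin(self):
        rng = np.random.default_rng(3)
        mask = rng.random((8, 8, 8)) > 0.9
        prev = mask
        for margin in (1.0, 2.5, 4.0):
            cur = expand_mask(mask, margin)
            assert (cur | prev).sum() == cur.sum()  # superset
            prev = cur

    def test_negative_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            expand_mask(np.ones((3, 3, 3), bool), -1.0)


class TestShellAt:
    def test_disjoint_from_ptv(self):
        mask = np.zeros((9, 9, 9), bool)
        mask[4, 4, 4] = True
        sh = shell_at(mask, 3.0, 2.0)
        assert not (sh & mask).any()

    def test_single_voxel_distance_band(self):
        # 1 mm grid: members must have center distance in (9, 11]
        mask = np.zeros((25, 25, 25), bool)
        mask[12, 12, 12] = True
        sh = shell_at(mask, 10.0, 2.0)
        pts = np.argwhere(sh) - 12
        d = np.linalg.norm(pts, axis=1)
        assert sh.any()
        assert (d > 9.0).all() and (d <= 11.0).all()

    def test_full_thickness_equals_expansion_difference(self):
        mask = np.zeros((21, 21, 21), bool)
        mask[10, 10, 10] = True
        dist = 4.0
        sh = shell_at(mask, dist, 2 * dist)
        expanded = expand_mask(mask, 2 * dist)
        assert np.array_equal(sh, expanded & ~mask)

    def test_empty_ptv_rejected(self):
        with pytest.raises(ValueError, match="nonempty"):
            shell_at(np.zeros((4, 4, 4), bool), 5.0, 2.0)


class TestSkinRing:
    def test_cube_outer_two_layers(self):
        body = np.zeros((24, 24, 24), bool)
        body[2:22, 2:22, 2:22] = True       # solid 20-voxel cube, 1 mm voxels
        ring = skin_ring(body, 2.0)
        inner = np.zeros_like(body)
        inner[4:20, 4:20, 4:20] = True
        assert np.array_equal(ring, body & ~inner)

    def test_saturates_to_whole_body(self):
        body = np.zeros((10, 10, 10), bool)
        body[3:7, 3:7, 3:7] = True
        assert np.array_equal(skin_ring(body, 100.0), body)

    def test_subset_of_body(self):
        rng = np.random.default_rng(5)
        body = expand_mask(rng.random((12, 12, 12)) > 0.97, 2.5)
        ring = skin_ring(body, 3.0)
        assert not (ring & ~body).any()


class TestGenerator:
    def test_required_structures_present_and_contained(self, default_phantom):
        ph = default_phantom
        for name in ("body", "ptv", "bladder", "small_bowel", "rectum",
                     "sigmoid", "shell_3mm", "shell_40mm", "skin_ring",
                     "unspecified_tissue"):
            assert ph.mask(name).any(), name
        body = ph.mask("body")
        assert not (ph.mask("ptv") & ~body).any()
        assert not (ph.mask("skin_ring") & ~body).any()

    def test_determinism(self):
        a = lp.generate_phantom(7)
        b = lp.generate_phantom(7)
        assert a.names == b.names
        for name in a.names:
            assert np.array_equal(a.mask(name), b.mask(name)), name

    def test_derived_structure_algebra(self, default_phantom):
        ph = default_phantom
        ptv = ph.mask("ptv")
        for d in (3, 15, 25, 40):
            assert not (ph.mask(f"shell_{d}mm") & ptv).any()
        assert not (ph.mask("unspecified_tissue") & ptv).any()
        for organ in ("small_bowel", "rectum", "sigmoid"):
            assert not (ph.mask("unspecified_tissue") & ph.mask(organ)).any()

    def test_concavity_orders_hull_fill(self):
        # hull-fill fraction non-increasing in concavity; strict at extremes
        for seed in range(1, 6):
            fills = []
            for c in (0.0, 0.3, 0.6, 0.9):
                ph = lp.generate_phantom(seed, PhantomParams(concavity=c))
                fills.append(hull_fill_fraction(ph.mask("ptv"), ph.grid))
            assert all(a >= b - 1e-9 for a, b in zip(fills, fills[1:])), (seed, fills)
            assert fills[0] > fills[-1], (seed, fills)

    def test_param_validation(self):
        with pytest.raises(ValueError, match="concavity"):
            lp.generate_phantom(1, PhantomParams(concavity=1.5))
        with pytest.raises(ValueError, match="margin"):
            lp.generate_phantom(1, PhantomParams(margin_mm=-1))
        with pytest.raises(ValueError, match="grid too coarse"):
            small = GridSpec((10, 10, 10), (5.0, 5.0, 5.0))
            lp.generate_phantom(1, PhantomParams(grid=small))

    def test_colon_optional(self):
        ph = lp.generate_phantom(2, PhantomParams(with_colon=True))
        assert "colon" in ph.structures and ph.mask("colon").any()
        assert "colon" not in lp.generate_phantom(2).structures


def test_nifti_round_trip(tmp_path, default_phantom):
    out = lp.save_phantom(default_phantom, tmp_path / "ph")
    back = lp.load_phantom(out)
    assert back.grid == default_phantom.grid
    assert back.seed == default_phantom.seed
    for name in default_phantom.names:
        assert np.array_equal(back.mask(name), default_phantom.mask(name))
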