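"""Volume I/O, orientation handling and standard-space resampling."""

import struct

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from longbrain.grid import (ImageGrid, Orientation, StandardSpace,
                            VolumeFormatError, canonical_orientation,
                            enumerate_orientations, read_volume, reorient,
                            resample_standard, to_ras, write_volume)


def _brute_force_right_handed():
    """Independent enumeration: all 6 x 8 permutation/flip combos, keeping
    those whose signed permutation matrix has determinant +1."""
    import itertools
    count = 0
    for perm in itertools.permutations(range(3)):
        for flips in itertools.product((1, -1), repeat=3):
            m = np.zeros((3, 3))
            for a in range(3):
                m[perm[a], a] = flips[a]
            if np.isclose(np.linalg.det(m), 1.0):
                count += 1
    return count


class TestOrientations:
    def test_identity_is_enumerated(self):
        assert Orientation((0, 1, 2), (1, 1, 1)) in enumerate_orientations()

    def test_right_handed_count_matches_brute_force(self):
        assert len(enumerate_orientations()) == _brute_force_right_handed() == 24

    def test_left_handed_rejected(self):
        with pytest.raises(ValueError):
            Orientation((0, 1, 2), (-1, 1, 1))

    def test_group_closure_under_squaring(self):
        mats = {tuple(np.round(o.matrix.flat).astype(int)): o
                for o in enumerate_orientations()}
        for o in enumerate_orientations():
            sq = o.matrix @ o.matrix
            assert tuple(np.round(sq.flat).astype(int)) in mats


class TestReorient:
    @pytest.fixture
    def ramp(self):
        return ImageGrid(np.arange(3 * 4 * 5, dtype=float).reshape(3, 4, 5),
                         spacing=(1.0, 2.0, 1.5), origin=(5.0, -3.0, 2.0))

    def test_identity_changes_nothing(self, ramp):
        out = reorient(ramp, Orientation((0, 1, 2), (1, 1, 1)))
        np.testing.assert_array_equal(out.voxels, ramp.voxels)
        np.testing.assert_allclose(out.affine, ramp.affine)

    def test_double_flip_is_involution(self, ramp):
        o = Orientation((0, 1, 2), (-1, -1, 1))
        twice = reorient(reorient(ramp, o), o)
        np.testing.assert_array_equal(twice.voxels, ramp.voxels)
        np.testing.assert_allclose(twice.affine, ramp.affine, atol=1e-12)

    def test_world_coordinate_of_max_voxel_preserved(self, ramp):
        o = Orientation((1, 2, 0), (1, 1, 1))
        out = reorient(ramp, o)
        mi = np.unravel_index(np.argmax(ramp.voxels), ramp.shape)
        mo = np.unravel_index(np.argmax(out.voxels), out.shape)
        np.testing.assert_allclose(ramp.index_to_world(mi),
                                   out.index_to_world(mo), atol=1e-12)

    @settings(max_examples=24, deadline=None)
    @given(st.integers(0, 23))
    def test_multiset_of_values_preserved(self, idx):
        img = ImageGrid(np.arange(24, dtype=float).reshape(2, 3, 4))
        out = reorient(img, enumerate_orientations()[idx])
        assert sorted(out.voxels.ravel()) == sorted(img.voxels.ravel())

    def test_canonicalization_reaches_identity_direction(self, ramp):
        scrambled = reorient(ramp, Orientation((2, 0, 1), (-1, 1, -1)))
        back = to_ras(scrambled)
        np.testing.assert_allclose(back.direction, np.eye(3), atol=1e-12)
        np.testing.assert_array_equal(back.voxels, ramp.voxels)

    def test_unknown_orientation_requires_explicit_choice(self):
        img = ImageGrid(np.zeros((2, 2, 2)), orientation_known=False)
        with pytest.raises(ValueError):
            canonical_orientation(img)


class TestIO:
    def test_nifti_round_trip(self, tmp_path, rng):
        img = ImageGrid(rng.random((5, 6, 7)).astype(np.float32),
                        spacing=(1.0, 1.2, 0.8), origin=(-2.0, 3.0, 0.5))
        write_volume(img, tmp_path / "x.nii.gz")
        back = read_volume(tmp_path / "x.nii.gz")
        np.testing.assert_allclose(back.voxels, img.voxels, rtol=1e-6)
        np.testing.assert_allclose(back.spacing, img.spacing, atol=1e-6)
        np.testing.assert_allclose(back.origin, img.origin, atol=1e-5)

    def test_integer_round_trip_bit_exact(self, tmp_path):
        img = ImageGrid(np.arange(8, dtype=np.int16).reshape(2, 2, 2))
        write_volume(img, tmp_path / "i.nii")
        np.testing.assert_array_equal(read_volume(tmp_path / "i.nii").voxels,
                                      img.voxels)

    def test_zero_volume(self, tmp_path):
        img = ImageGrid(np.zeros((2, 2, 2), dtype=np.uint8))
        write_volume(img, tmp_path / "z.nii")
        back = read_volume(tmp_path / "z.nii")
        assert back.voxels.shape == (2, 2, 2)
        assert np.count_nonzero(back.voxels) == 0

    def test_analyze_ramp_against_handwritten_header(self, tmp_path):
        """Cross-check the Analyze 7.5 reader against an independently
        written 348-byte header + raw int16 ramp payload."""
        shape = (3, 4, 5)
        n = int(np.prod(shape))
        hdr = bytearray(348)
        struct.pack_into("<i", hdr, 0, 348)                   # sizeof_hdr
        struct.pack_into("<8h", hdr, 40, 3, *shape, 1, 1, 1, 1)  # dim
        struct.pack_into("<h", hdr, 70, 4)                    # datatype int16
        struct.pack_into("<h", hdr, 72, 16)                   # bitpix
        struct.pack_into("<8f", hdr, 76, 0, 1.0, 1.5, 2.0, 1, 1, 1, 1)
        (tmp_path / "r.hdr").write_bytes(bytes(hdr))
        ramp = np.arange(n, dtype="<i2")
        (tmp_path / "r.img").write_bytes(ramp.tobytes())

        img = read_volume(tmp_path / "r.hdr")
        assert img.orientation_known is False
        np.testing.assert_allclose(img.spacing, (1.0, 1.5, 2.0))
        # scan order: fastest-varying first axis (Fortran layout on disk)
        np.testing.assert_array_equal(
            img.voxels, ramp.reshape(shape, order="F"))

    def test_analyze_write_read_round_trip(self, tmp_path):
        img = ImageGrid(np.arange(24, dtype=np.int16).reshape(2, 3, 4),
                        spacing=(1.0, 2.0, 3.0))
        write_volume(img, tmp_path / "a.hdr")
        back = read_volume(tmp_path / "a.hdr")
        np.testing.assert_array_equal(back.voxels, img.voxels)
        np.testing.assert_allclose(back.spacing, img.spacing)

    def test_unreadable_file_raises_format_error(self, tmp_path):
        bad = tmp_path / "bad.nii"
        bad.write_bytes(b"not a nifti at all")
        with pytest.raises(VolumeFormatError):
            read_volume(bad)


class TestResample:
    def test_identity_on_standard_geometry(self, rng):
        std = StandardSpace((16, 16, 16), (1.0, 1.0, 1.0))
        img = ImageGrid(rng.random((16, 16, 16)), origin=(-7.5, -7.5, -7.5))
        out = resample_standard(img, std)
        np.testing.assert_allclose(out.voxels, img.voxels, atol=1e-6)

    def test_constant_input_stays_constant_inside_fov(self):
        img = ImageGrid(np.full((10, 10, 10), 3.5), spacing=(2.0, 2.0, 2.0),
                        origin=(-9.0, -9.0, -9.0))
        out = resample_standard(img, StandardSpace((12, 12, 12)))
        center = out.voxels[3:9, 3:9, 3:9]
        np.testing.assert_allclose(center, 3.5, atol=1e-6)

    def test_sphere_volume_preserved_across_spacing_change(self):
        shape = (32, 32, 32)
        ii, jj, kk = np.meshgrid(*[np.arange(s) for s in shape],
                                 indexing="ij")
        r = np.sqrt((ii - 15.5) ** 2 + (jj - 15.5) ** 2 + (kk - 15.5) ** 2)
        mask = (r * 2.0 < 20.0).astype(float)        # 2 mm voxels
        img = ImageGrid(mask, spacing=(2.0, 2.0, 2.0), origin=(-31.0,) * 3)
        vol_in = mask.sum() * 8.0
        out = resample_standard(img, StandardSpace((64, 64, 64)))
        vol_out = (out.voxels >= 0.5).sum() * 1.0
        assert abs(vol_out - vol_in) / vol_in < 0.03

    def test_idempotent_on_own_output(self, rng):
        img = ImageGrid(rng.random((20, 20, 20)), spacing=(2.0, 2.0, 2.0),
                        origin=(-19.0,) * 3)
        std = StandardSpace((24, 24, 24))
        once = resample_standard(img, std)
        twice = resample_standard(once, std)
        np.testing.assert_allclose(twice.voxels, once.voxels, atol=1e-6)
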