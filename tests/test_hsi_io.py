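"""ENVI codec, calibration, and cube/matrix conversion."""

import numpy as np
import pytest

from xhclust import (
    CalibrationSet,
    SpectralCube,
    SpectralMatrix,
    calibrate_reflectance,
    cube_to_matrix,
    matrix_to_map,
    read_envi_cube,
    write_envi_cube,
)
from xhclust.errors import (
    CalibrationError,
    ConsistencyError,
    CorruptFileError,
    FormatError,
    ParameterError,
)


class TestEnviRoundTrip:
    @pytest.mark.parametrize("interleave", ["bsq", "bil", "bip"])
    def test_float32_bit_exact(self, small_cube, tmp_path, interleave):
        path = tmp_path / f"cube_{interleave}.img"
        write_envi_cube(small_cube, path, interleave=interleave)
        back = read_envi_cube(path)
        assert np.array_equal(back.values, small_cube.values)
        assert np.allclose(back.wavelengths, small_cube.wavelengths)

    def test_interleave_invariance(self, small_cube, tmp_path):
        cubes = []
        for interleave in ("bsq", "bil", "bip"):
            p = tmp_path / f"c_{interleave}.img"
            write_envi_cube(small_cube, p, interleave=interleave)
            cubes.append(read_envi_cube(p).values)
        assert np.array_equal(cubes[0], cubes[1])
        assert np.array_equal(cubes[1], cubes[2])

    def test_uint16_round_trip(self, tmp_path):
        values = np.arange(24, dtype=np.uint16).reshape(2, 3, 4)
        cube = SpectralCube(values, [400.0, 500.0, 600.0, 700.0])
        write_envi_cube(cube, tmp_path / "u.img", dtype=np.uint16)
        assert np.array_equal(read_envi_cube(tmp_path / "u.img").values, values)

    def test_nan_rejected(self, tmp_path):
        values = np.full((2, 2, 2), np.nan)
        cube = SpectralCube(values, [500.0, 600.0])
        with pytest.raises(ParameterError):
            write_envi_cube(cube, tmp_path / "bad.img")

    def test_wavelength_band_mismatch_is_corrupt(self, small_cube, tmp_path):
        path = tmp_path / "c.img"
        write_envi_cube(small_cube, path)
        hdr = path.with_suffix(".hdr")
        hdr.write_text(hdr.read_text().replace("bands = 3", "bands = 5")
                       .replace("lines = 4", "lines = 4"))
        with pytest.raises(CorruptFileError):
            read_envi_cube(path)

    def test_missing_wavelengths_is_format_error(self, small_cube, tmp_path):
        path = tmp_path / "c.img"
        write_envi_cube(small_cube, path)
        hdr = path.with_suffix(".hdr")
        text = "\n".join(l for l in hdr.read_text().splitlines()
                         if not l.startswith("wavelength ="))
        hdr.write_text(text)
        with pytest.raises(FormatError):
            read_envi_cube(path)


class TestCalibration:
    @pytest.fixture
    def refs(self, rng):
        shape = (5, 6, 4)
        dark = rng.uniform(50, 60, size=shape)
        white = dark + rng.uniform(500, 800, size=shape)
        wl = [450.0, 550.0, 650.0, 750.0]
        return shape, wl, SpectralCube(white, wl), SpectralCube(dark, wl)

    def test_dark_maps_to_zero_and_white_to_one(self, refs):
        shape, wl, white, dark = refs
        cal = CalibrationSet(white=white, dark=dark)
        zero = calibrate_reflectance(SpectralCube(dark.values.copy(), wl), cal)
        one = calibrate_reflectance(SpectralCube(white.values.copy(), wl), cal)
        assert np.allclose(zero.values, 0.0)
        assert np.allclose(one.values, 1.0)

    def test_linearity_quarter_point(self, refs):
        shape, wl, white, dark = refs
        cal = CalibrationSet(white=white, dark=dark)
        raw = SpectralCube(dark.values + 0.25 * (white.values - dark.values), wl)
        out = calibrate_reflectance(raw, cal)
        assert np.allclose(out.values, 0.25)

    def test_affine_invariance(self, refs, rng):
        shape, wl, white, dark = refs
        raw = SpectralCube(rng.uniform(100, 400, size=shape), wl)
        base = calibrate_reflectance(raw, CalibrationSet(white, dark))
        a, b = 2.5, 17.0
        scaled = calibrate_reflectance(
            SpectralCube(a * raw.values + b, wl),
            CalibrationSet(SpectralCube(a * white.values + b, wl),
                           SpectralCube(a * dark.values + b, wl)))
        assert np.allclose(scaled.values, base.values)

    def test_per_band_vector_references(self, rng):
        wl = [500.0, 600.0]
        raw = SpectralCube(rng.uniform(100, 200, size=(3, 3, 2)), wl)
        cal = CalibrationSet(white=np.array([300.0, 400.0]),
                             dark=np.array([10.0, 20.0]))
        out = calibrate_reflectance(raw, cal)
        expect = (raw.values - [10, 20]) / ([300, 400] - np.array([10, 20]))
        assert np.allclose(out.values, expect)

    def test_nonpositive_denominator_names_band(self, rng):
        wl = [500.0, 600.0]
        raw = SpectralCube(rng.uniform(size=(2, 2, 2)), wl)
        cal = CalibrationSet(white=np.array([300.0, 20.0]),
                             dark=np.array([10.0, 20.0]))
        with pytest.raises(CalibrationError, match="1"):
            calibrate_reflectance(raw, cal)


class TestCubeMatrixConversion:
    def test_mask_drops_columns(self, small_cube):
        excluded = np.zeros((4, 4), dtype=bool)
        excluded[0, 0] = True
        mat = cube_to_matrix(small_cube, excluded)
        assert mat.n_signatures == 15
        assert (0, 0) not in {(r, c) for _, r, c in mat.pixel_index}

    def test_no_mask_keeps_all_row_major(self, small_cube):
        mat = cube_to_matrix(small_cube)
        assert mat.n_signatures == 16
        coords = [(r, c) for _, r, c in mat.pixel_index]
        assert coords == sorted(coords)
        # column j holds the spectrum of its back-mapped pixel
        for j in (0, 5, 15):
            _, r, c = mat.pixel_index[j]
            assert np.allclose(mat.X[:, j], small_cube.values[r, c])

    def test_all_masked_is_error(self, small_cube):
        with pytest.raises(ParameterError):
            cube_to_matrix(small_cube, np.ones((4, 4), dtype=bool))

    def test_round_trip_through_map(self, small_cube, rng):
        excluded = rng.uniform(size=(4, 4)) < 0.3
        excluded[0, 1] = False  # keep at least one pixel
        mat = cube_to_matrix(small_cube, excluded)
        labels = rng.integers(1, 4, size=mat.n_signatures)
        cmap = matrix_to_map(labels, mat.pixel_index, (4, 4), k=3)
        assert np.all(cmap.labels[excluded] == 0)
        for lab, (_, r, c) in zip(labels, mat.pixel_index):
            assert cmap.labels[r, c] == lab

    def test_single_pixel_map(self):
        cmap = matrix_to_map([2], [(0, 0, 0)], (1, 1), k=3)
        assert cmap.labels.shape == (1, 1) and cmap.labels[0, 0] == 2

    def test_duplicate_index_rejected(self):
        with pytest.raises(ConsistencyError):
            matrix_to_map([1, 2], [(0, 0, 0), (0, 0, 0)], (2, 2))

    def test_out_of_bounds_rejected(self):
        with pytest.raises(ConsistencyError):
            matrix_to_map([1], [(0, 5, 0)], (2, 2))


class TestSpectralMatrixInvariants:
    def test_row_count_must_match_wavelengths(self):
        with pytest.raises(ParameterError):
            SpectralMatrix(np.zeros((3, 2)), [(0, 0, 0), (0, 0, 1)], [500.0, 600.0])
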