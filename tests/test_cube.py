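"""ENVI round trips, black/white calibration, segmentation and extraction."""

import numpy as np
import pytest

from leafwater import (
    CalibrationFrames,
    HyperCube,
    SimConfig,
    calibrate,
    mean_spectrum,
    read_envi,
    segment_leaf,
    simulate_cube,
    write_envi,
)
from leafwater.cube import read_mask_png, write_mask_png
from leafwater.grid import WavelengthGrid, default_grid


@pytest.fixture
def tiny_cube(rng):
    grid = WavelengthGrid(np.linspace(1000.0, 1100.0, 6))
    return HyperCube(data=rng.random((4, 4, 6)), grid=grid)


@pytest.mark.parametrize("interleave", ["bil", "bip", "bsq"])
@pytest.mark.parametrize("dtype", [np.float64, np.float32])
def test_envi_round_trip_lossless(tmp_path, tiny_cube, interleave, dtype):
    cube = HyperCube(data=tiny_cube.data.astype(dtype), grid=tiny_cube.grid)
    hdr = tmp_path / f"cube_{interleave}.hdr"
    write_envi(cube, hdr, interleave=interleave)
    back = read_envi(hdr)
    np.testing.assert_array_equal(back.data, cube.data)
    np.testing.assert_allclose(back.grid.centers_nm, cube.grid.centers_nm, atol=1e-6)


def test_envi_interleaves_agree(tmp_path, tiny_cube):
    cubes = []
    for interleave in ("bil", "bsq"):
        hdr = tmp_path / f"c_{interleave}.hdr"
        write_envi(tiny_cube, hdr, interleave=interleave)
        cubes.append(read_envi(hdr).data)
    np.testing.assert_array_equal(cubes[0], cubes[1])


def test_envi_header_validation(tmp_path, tiny_cube):
    hdr = tmp_path / "bad.hdr"
    write_envi(tiny_cube, hdr)
    text = hdr.read_text()
    # wavelength list shorter than declared band count
    broken = text.replace(f"{tiny_cube.grid.centers_nm[-1]:.6f}", "").replace(", }", " }")
    hdr.write_text(broken)
    with pytest.raises(ValueError, match="wavelength"):
        read_envi(hdr)
    hdr.write_text("\n".join(l for l in text.splitlines() if not l.startswith("wavelength =")))
    with pytest.raises(ValueError, match="wavelength"):
        read_envi(hdr)


@pytest.mark.parametrize("t,expected", [(1.0, 1.0), (0.0, 0.0), (0.5, 0.5), (2.5, 2.5)])
def test_calibration_affine_equivariance(rng, t, expected):
    """I = B + t (W - B) must calibrate to R = t everywhere."""
    grid = WavelengthGrid(np.linspace(900, 1700, 5))
    white = rng.random((1, 6, 5)) + 2.0
    dark = rng.random((1, 6, 5))
    raw = dark + t * (white - dark)
    frames = CalibrationFrames(raw=np.broadcast_to(raw, (3, 6, 5)).copy(), white=white, dark=dark, grid=grid)
    out = calibrate(frames)
    np.testing.assert_allclose(out.data, expected, atol=1e-12)


def test_calibration_rejects_nonpositive_denominator(rng):
    grid = WavelengthGrid(np.linspace(900, 1700, 4))
    white = np.ones((1, 3, 4))
    dark = np.ones((1, 3, 4))  # W - B = 0
    with pytest.raises(ValueError, match="non-positive"):
        calibrate(CalibrationFrames(raw=np.ones((2, 3, 4)), white=white, dark=dark, grid=grid))


def test_segment_leaf_supervised_accuracy(small_config):
    cube, _ = simulate_cube(32, 32, small_config, seed=8)
    truth = cube.mask.copy()
    rng = np.random.default_rng(1)
    leaf = np.argwhere(truth)[rng.choice(truth.sum(), 20, replace=False)]
    bg = np.argwhere(~truth)[rng.choice((~truth).sum(), 20, replace=False)]
    coords = np.vstack([leaf, bg])
    labels = np.array([True] * 20 + [False] * 20)
    blank = HyperCube(data=cube.data, grid=cube.grid)  # mask withheld
    mask = segment_leaf(blank, labeled_pixels=(coords, labels))
    assert (mask == truth).mean() >= 0.98


def test_segment_leaf_unsupervised_and_scale_invariance(small_config):
    cube, _ = simulate_cube(32, 32, small_config, seed=8)
    truth = cube.mask.copy()
    blank = HyperCube(data=cube.data, grid=cube.grid)
    mask = segment_leaf(blank)
    assert (mask == truth).mean() >= 0.95
    # band-wise constant rescaling must not move the ratio-rule mask
    scale = np.linspace(0.5, 2.0, cube.data.shape[2])
    scaled = HyperCube(data=cube.data * scale[None, None, :], grid=cube.grid)
    np.testing.assert_array_equal(segment_leaf(scaled), mask)


def test_segment_leaf_all_background_warns(grid80, rng):
    data = np.clip(0.06 + rng.normal(0, 0.01, size=(16, 16, 80)), 0, None)
    cube = HyperCube(data=data, grid=grid80)
    with pytest.warns(UserWarning, match="empty"):
        mask = segment_leaf(cube)
    assert not mask.any()


def test_segment_leaf_single_class_training_errors(tiny_cube):
    coords = np.array([[0, 0], [1, 1]])
    with pytest.raises(ValueError, match="both"):
        segment_leaf(tiny_cube, labeled_pixels=(coords, np.array([True, True])))


def test_mean_spectrum_values_and_oracle(tiny_cube, rng):
    uniform = HyperCube(data=np.full((3, 3, 6), 0.4), grid=tiny_cube.grid)
    np.testing.assert_allclose(mean_spectrum(uniform), 0.4, atol=1e-15)

    two = HyperCube(data=np.zeros((1, 2, 6)), grid=tiny_cube.grid)
    two.data[0, 0] = 0.2
    two.data[0, 1] = 0.6
    np.testing.assert_allclose(mean_spectrum(two), 0.4, atol=1e-15)

    mask = rng.random((4, 4)) > 0.4
    cube = HyperCube(data=tiny_cube.data, grid=tiny_cube.grid, mask=mask)
    loop = np.zeros(6)
    for r in range(4):
        for c in range(4):
            if mask[r, c]:
                loop += cube.data[r, c]
    np.testing.assert_allclose(mean_spectrum(cube), loop / mask.sum(), atol=1e-12)


def test_mean_spectrum_empty_mask_errors(tiny_cube):
    cube = HyperCube(data=tiny_cube.data, grid=tiny_cube.grid, mask=np.zeros((4, 4), bool))
    with pytest.raises(ValueError, match="empty"):
        mean_spectrum(cube)


def test_masking_commutes_with_calibration(rng):
    """Masking before or after calibration yields the same mean spectrum."""
    grid = WavelengthGrid(np.linspace(900, 1700, 5))
    white = rng.random((1, 6, 5)) + 2.0
    dark = rng.random((1, 6, 5))
    raw = dark + rng.random((4, 6, 5)) * (white - dark)
    mask = rng.random((4, 6)) > 0.5
    frames = CalibrationFrames(raw=raw, white=white, dark=dark, grid=grid)
    cal = calibrate(frames)
    after = mean_spectrum(HyperCube(data=cal.data, grid=grid, mask=mask))
    before = mean_spectrum(
        HyperCube(data=calibrate(frames).data, grid=grid, mask=mask)
    )
    np.testing.assert_allclose(after, before, atol=1e-14)


def test_mask_png_round_trip(tmp_path, rng):
    mask = rng.random((10, 12)) > 0.5
    path = tmp_path / "mask.png"
    write_mask_png(mask, path)
    np.testing.assert_array_equal(read_mask_png(path), mask)
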