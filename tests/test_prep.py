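"""Preprocessing operators against closed forms and brute-force oracles,
plus the PLSR-based method-ranking harness."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from leafwater import PrepMethod, SimConfig, compare_preprocessing, simulate_sample_table
from leafwater.grid import default_grid
from leafwater.prep import first_derivative, msc, normalize, savitzky_golay, snv
from leafwater.synth import SampleTable


def test_snv_row_example():
    np.testing.assert_allclose(snv(np.array([[1.0, 2.0, 3.0]])), [[-1.0, 0.0, 1.0]], atol=1e-12)


def test_snv_moments_and_idempotence(rng):
    X = rng.random((8, 40))
    out = snv(X)
    np.testing.assert_allclose(out.mean(axis=1), 0.0, atol=1e-10)
    np.testing.assert_allclose(out.std(axis=1, ddof=1), 1.0, atol=1e-10)
    np.testing.assert_allclose(snv(out), out, atol=1e-10)


@settings(derandomize=True, max_examples=50)
@given(a=st.floats(-5, 5), b=st.floats(0.1, 10), seed=st.integers(0, 100))
def test_snv_affine_invariance(a, b, seed):
    """SNV(a + b x) = SNV(x) for any positive-scale row-affine transform."""
    X = np.random.default_rng(seed).random((3, 20))
    np.testing.assert_allclose(snv(a + b * X), snv(X), atol=1e-8)


def test_snv_constant_row_errors():
    with pytest.raises(ValueError, match="constant"):
        snv(np.array([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]]))


def test_msc_identity_and_affine_inversion(rng):
    ref = rng.random(30) + 0.5
    X = np.vstack([ref, 2.0 * ref + 0.1])
    out = msc(X, reference=ref)
    np.testing.assert_allclose(out[0], ref, atol=1e-10)
    np.testing.assert_allclose(out[1], ref, atol=1e-10)


def test_msc_matches_least_squares_oracle(rng):
    X = rng.random((6, 25)) + 0.2
    ref = X.mean(axis=0)
    out = msc(X)
    for i in range(6):
        A = np.column_stack([np.ones(25), ref])
        (a, b), *_ = np.linalg.lstsq(A, X[i], rcond=None)
        np.testing.assert_allclose(out[i], (X[i] - a) / b, atol=1e-10)


def test_msc_mean_spectrum_is_fixed_point(rng):
    X = rng.random((7, 30)) + 0.3
    out = msc(X)
    # the reference (column mean) regresses onto itself with (a, b) = (0, 1)
    np.testing.assert_allclose(msc(X.mean(axis=0)[None, :], reference=X.mean(axis=0))[0], X.mean(axis=0), atol=1e-10)
    assert out.shape == X.shape


def test_savgol_polynomial_reproduction(grid80):
    lam = grid80.centers_nm
    quad = (2.0 + 0.01 * lam + 1e-5 * lam**2)[None, :]
    out = savitzky_golay(quad, window=7, polyorder=2, grid=grid80)
    np.testing.assert_allclose(out[0, 3:-3], quad[0, 3:-3], atol=1e-8)


def test_savgol_first_derivative_of_line(grid80):
    s = 0.002  # reflectance per nm
    row = (s * grid80.centers_nm)[None, :]
    out = savitzky_golay(row, window=7, polyorder=2, deriv_order=1, grid=grid80)
    np.testing.assert_allclose(out[0, 3:-3], s, atol=1e-10)


def test_savgol_matches_sliding_fit_oracle(grid80, rng):
    """Interior SG output equals an explicit local polynomial fit."""
    row = rng.random(80)
    window, poly = 9, 3
    out = savitzky_golay(row[None, :], window, poly, grid=grid80)[0]
    half = window // 2
    x = np.arange(-half, half + 1, dtype=float)
    for k in range(half, 80 - half, 7):
        coef = np.polyfit(x, row[k - half : k + half + 1], poly)
        assert out[k] == pytest.approx(np.polyval(coef, 0.0), abs=1e-9)


def test_savgol_rejects_even_window(grid80, rng):
    with pytest.raises(ValueError, match="odd"):
        savitzky_golay(rng.random((2, 80)), window=8, grid=grid80)


def test_normalize_and_fd(grid80):
    np.testing.assert_allclose(normalize(np.array([[2.0, 4.0, 6.0]])), [[0.0, 0.5, 1.0]], atol=1e-12)
    with pytest.raises(ValueError, match="constant"):
        normalize(np.array([[3.0, 3.0]]))
    s = 0.004
    line = (s * grid80.centers_nm + 1.0)[None, :]
    np.testing.assert_allclose(first_derivative(line, grid80)[0], s, atol=1e-12)


def test_fd_matches_loop_oracle(grid80, rng):
    row = rng.random(80)
    out = first_derivative(row[None, :], grid80)[0]
    lam = grid80.centers_nm
    loop = np.empty(80)
    loop[0] = (row[1] - row[0]) / (lam[1] - lam[0])
    loop[-1] = (row[-1] - row[-2]) / (lam[-1] - lam[-2])
    for k in range(1, 79):
        loop[k] = (row[k + 1] - row[k - 1]) / (lam[k + 1] - lam[k - 1])
    np.testing.assert_allclose(out, loop, atol=1e-12)


def _linear_table(n=100, seed=7):
    """Noise-free table whose wc is exactly linear in the spectra."""
    grid = default_grid(80, 900.0, 1700.0)
    lam = grid.centers_nm
    x = (lam - 900.0) / 800.0
    base = 0.65 + 0.25 * x - 0.10 * x**2
    prof = np.exp(-0.5 * ((lam - 1440.0) / 80.0) ** 2)
    prof = prof - prof.mean()
    rng = np.random.default_rng(seed)
    wc = rng.uniform(0.2, 0.8, n)
    X = base[None, :] - 0.05 * wc[:, None] * prof[None, :]
    return SampleTable([f"s{i}" for i in range(n)], grid, X, wc, ["peach"] * n, ["calibration"] * n)


def test_all_methods_near_perfect_on_noiseless_linear_table():
    ranking = compare_preprocessing(_linear_table(), seed=0)
    assert (ranking["r2_cv"] > 0.999).all(), ranking


def test_scatter_injection_favors_snv_or_msc():
    """With strong per-spectrum scatter and a tight component budget, SNV or
    MSC must out-rank raw spectra by RMSECV in at least 8 of 10 replicates."""
    wins = 0
    for s in range(10):
        cfg = SimConfig(n_bands=80, scatter_mult_sd=0.15, scatter_add_sd=0.08, noise_sd=2e-3)
        tab = simulate_sample_table(120, cfg, seed=s)
        ranking = compare_preprocessing(
            tab, [PrepMethod("none"), PrepMethod("SNV"), PrepMethod("MSC")], max_components=2, seed=s
        )
        r = {row["method"]: row["rmsecv"] for _, row in ranking.iterrows()}
        wins += (r["SNV"] < r["none"]) or (r["MSC"] < r["none"])
    assert wins >= 8


def test_duplicate_methods_produce_identical_rows(small_table):
    ranking = compare_preprocessing(small_table, [PrepMethod("SNV"), PrepMethod("SNV")], seed=1)
    a, b = ranking.iloc[0], ranking.iloc[1]
    assert a.drop("method").tolist() == b.drop("method").tolist()


def test_fold_assignment_depends_only_on_n_k_seed():
    from leafwater._pls import kfold_indices

    f1 = kfold_indices(57, 10, 3)
    f2 = kfold_indices(57, 10, 3)
    for a, b in zip(f1, f2):
        np.testing.assert_array_equal(a, b)
    sizes = sorted(len(f) for f in f1)
    assert sizes[-1] - sizes[0] <= 1
    assert sorted(np.concatenate(f1).tolist()) == list(range(57))


def test_prep_method_validation():
    with pytest.raises(ValueError):
        PrepMethod("SNV+SG")
    with pytest.raises(ValueError):
        PrepMethod("SG", sg_window=4)
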