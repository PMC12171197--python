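"""NISDI, the two-band index families, Pearson screening and pair search."""

import numpy as np
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

from leafwater import PlantedSignal, SimConfig, simulate_sample_table
from leafwater.grid import WavelengthGrid, default_grid
from leafwater.vindex import (
    NISDI_REFL_NM,
    NISDI_SLOPE_NM,
    fit_index_model,
    nisdi,
    nisdi_table,
    pair_index,
    pearson,
    search_pairs,
    slope,
)


def test_slope_linear_and_constant(grid80):
    lam = grid80.centers_nm
    d = slope(0.001 * lam, grid80).d_values
    np.testing.assert_allclose(d, 0.001, atol=1e-12)
    np.testing.assert_allclose(slope(np.full(80, 0.3), grid80).d_values, 0.0, atol=1e-15)


def test_slope_matches_loop_oracle(grid80, rng):
    s = rng.random(80)
    lam = grid80.centers_nm
    d = slope(s, grid80).d_values
    for k in range(1, 79):
        assert d[k] == pytest.approx((s[k + 1] - s[k - 1]) / (lam[k + 1] - lam[k - 1]), abs=1e-12)
    assert d[0] == pytest.approx((s[1] - s[0]) / (lam[1] - lam[0]), abs=1e-12)


def test_slope_needs_three_bands():
    g = WavelengthGrid(np.array([1000.0, 1010.0]))
    with pytest.raises(ValueError):
        slope(np.array([0.1, 0.2]), g)


def test_nisdi_coefficients(grid80):
    # flat spectrum: D = 0 everywhere, R(1439) = 0.5 -> -1.9 * 0.5
    assert nisdi(np.full(80, 0.5), grid80) == pytest.approx(-0.95, abs=1e-12)
    # line through zero at the 1439 nm band with slope 0.001 / nm -> 1.3e3 * 0.001
    lam = grid80.centers_nm
    anchor = lam[grid80.nearest(NISDI_REFL_NM)]
    assert nisdi(0.001 * (lam - anchor), grid80) == pytest.approx(1.3, abs=1e-12)


@settings(derandomize=True, max_examples=50)
@given(alpha=st.floats(-3, 3), beta=st.floats(-3, 3), seed=st.integers(0, 50))
def test_nisdi_linearity(alpha, beta, seed):
    grid = default_grid(40, 900.0, 1700.0)
    r = np.random.default_rng(seed)
    s1, s2 = r.random(40), r.random(40)
    lhs = nisdi(alpha * s1 + beta * s2, grid)
    rhs = alpha * nisdi(s1, grid) + beta * nisdi(s2, grid)
    assert lhs == pytest.approx(rhs, abs=1e-9)


def test_nisdi_table_matches_per_sample_loop(small_table):
    vec = nisdi_table(small_table)
    for i in range(0, small_table.n_samples, 7):
        assert vec[i] == pytest.approx(nisdi(small_table.reflectance[i], small_table.grid), abs=1e-12)


def test_nisdi_requires_anchor_coverage():
    g = default_grid(16, 900.0, 1300.0)  # stops short of both anchors
    with pytest.raises(ValueError, match="anchor"):
        nisdi(np.ones(16), g)


def test_pair_index_values():
    assert pair_index("DVI", 0.8, 0.3) == pytest.approx(0.5)
    assert pair_index("RVI", 0.6, 0.2) == pytest.approx(3.0)
    assert pair_index("NDVI", 0.4, 0.4) == pytest.approx(0.0)
    assert np.isnan(pair_index("RVI", 0.5, 0.0))
    assert np.isnan(pair_index("NDVI", 0.5, -0.5))


def test_pearson_exact_cases():
    x = np.array([1.0, 2.0, 3.0, 4.0])
    r = pearson(x, x)
    assert r.r == pytest.approx(1.0) and r.p == 0.0
    assert pearson(x, -x).r == pytest.approx(-1.0)
    with pytest.raises(ValueError, match="constant"):
        pearson(x, np.full(4, 2.0))


def test_pearson_matches_scipy(rng):
    x = np.array([1.0, 2.0, 3.0])
    y = np.array([1.0, 2.0, 4.0])
    res = pearson(x, y)
    ref = scipy.stats.pearsonr(x, y)
    assert res.r == pytest.approx(0.982, abs=5e-4)
    assert res.r == pytest.approx(ref.statistic, abs=1e-12)
    assert res.p == pytest.approx(ref.pvalue, abs=1e-12)
    for _ in range(5):
        a, b = rng.normal(size=30), rng.normal(size=30)
        res = pearson(a, b)
        ref = scipy.stats.pearsonr(a, b)
        assert res.r == pytest.approx(ref.statistic, abs=1e-12)
        assert res.p == pytest.approx(ref.pvalue, rel=1e-9)


def test_search_recovers_planted_pair():
    import dataclasses

    # noise off, scatter on: only the planted pair is exactly affine in wc
    cfg = dataclasses.replace(SimConfig(n_bands=80), noise_sd=0.0)
    planted = PlantedSignal(band_a=12, band_b=55, alpha=2.0, beta=0.1)
    t = simulate_sample_table(50, cfg, planted=planted, seed=2)
    res = search_pairs(t, "DVI")
    assert (res.best_pair.band_i, res.best_pair.band_j) == (12, 55)
    assert res.best_abs_r == pytest.approx(1.0, abs=1e-10)


def test_search_heatmap_symmetry(small_table):
    for family in ("DVI", "NDVI"):
        heat = search_pairs(small_table, family).heatmap
        i, j = np.triu_indices(heat.shape[0], k=1)
        np.testing.assert_allclose(heat[i, j], heat[j, i], atol=1e-10)


def test_search_heatmap_matches_brute_force(small_config):
    t = simulate_sample_table(25, small_config, seed=6)
    t6 = type(t)(
        sample_ids=t.sample_ids,
        grid=WavelengthGrid(t.grid.centers_nm[:6]),
        reflectance=t.reflectance[:, :6],
        water_content=t.water_content,
        species=t.species,
        role=t.role,
    )
    for family in ("DVI", "RVI", "NDVI"):
        heat = search_pairs(t6, family).heatmap
        for i in range(6):
            for j in range(6):
                if i == j:
                    assert np.isnan(heat[i, j])
                    continue
                idx = pair_index(family, t6.reflectance[:, i], t6.reflectance[:, j])
                expect = abs(scipy.stats.pearsonr(idx, t6.water_content).statistic)
                assert heat[i, j] == pytest.approx(expect, abs=1e-10)


def test_search_abs_r_invariant_to_wc_affine(small_table):
    res1 = search_pairs(small_table, "DVI")
    shifted = type(small_table)(
        sample_ids=small_table.sample_ids,
        grid=small_table.grid,
        reflectance=small_table.reflectance,
        water_content=np.clip(0.3 + 0.5 * small_table.water_content, 0, 1),
        species=small_table.species,
        role=small_table.role,
    )
    res2 = search_pairs(shifted, "DVI")
    np.testing.assert_allclose(res1.heatmap, res2.heatmap, atol=1e-9)
    assert (res1.best_pair.band_i, res1.best_pair.band_j) == (res2.best_pair.band_i, res2.best_pair.band_j)


def test_search_rejects_constant_wc(small_table):
    bad = type(small_table)(
        sample_ids=small_table.sample_ids,
        grid=small_table.grid,
        reflectance=small_table.reflectance,
        water_content=np.full(small_table.n_samples, 0.5),
        species=small_table.species,
        role=small_table.role,
    )
    with pytest.raises(ValueError, match="constant"):
        search_pairs(bad, "DVI")


def test_fit_index_model_exact_and_oracle(rng):
    x = rng.random(50)
    y = 0.6 * x + 0.1
    model, m = fit_index_model(x, y)
    assert m.r2_cal == pytest.approx(1.0, abs=1e-12)
    assert m.rmse_cal == pytest.approx(0.0, abs=1e-10)
    # normal-equations oracle on noisy data
    y2 = y + rng.normal(0, 0.02, 50)
    model2, _ = fit_index_model(x, y2)
    A = np.column_stack([x, np.ones(50)])
    slope_ref, icpt_ref = np.linalg.lstsq(A, y2, rcond=None)[0]
    assert model2.slope == pytest.approx(slope_ref, abs=1e-10)
    assert model2.intercept == pytest.approx(icpt_ref, abs=1e-10)


def test_shuffled_index_has_no_predictive_power():
    """Permuting the index against wc destroys prediction R^2 (< 0.05 in >= 9/10 seeds)."""
    ok = 0
    for s in range(10):
        rng = np.random.default_rng(s)
        x = rng.random(200)
        y = 0.5 * x + 0.2 + rng.normal(0, 0.01, 200)
        xs = rng.permutation(x)
        _, m = fit_index_model(xs[:140], y[:140], xs[140:], y[140:])
        ok += m.r2_pred < 0.05
    assert ok >= 9


def test_fit_index_model_rejects_constant_index():
    with pytest.raises(ValueError, match="variance"):
        fit_index_model(np.full(10, 1.0), np.linspace(0, 1, 10))
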