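"""Posterior curves, functional ratios, crossings, extrema and WAIC."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import isogamm as ig
from isogamm.analysis import CurveDraws, RatioCurve


def fake_curve(draws, grid=None, **kw):
    grid = np.arange(0.0, 91.0, 1.0) if grid is None else grid
    return CurveDraws(grid=grid, draws=np.asarray(draws, dtype=float), **kw)


def test_degenerate_fit_gives_constant_curves(small_fit):
    fit = small_fit
    coef = np.zeros_like(fit.coef)
    coef[..., 0] = 42.0        # beta0 only; all smooth coefficients zero
    degenerate = ig.HGAMFit(design=fit.design, coef=coef,
                            variances=fit.variances, loglik_=fit.loglik_,
                            n_iter=fit.n_iter, n_warmup=fit.n_warmup,
                            seed=fit.seed)
    cd = ig.posterior_curve(degenerate, np.linspace(10, 80, 15))
    np.testing.assert_allclose(cd.draws, 42.0, atol=1e-10)


def test_grid_shape_contract(small_fit):
    cd = ig.posterior_curve(small_fit, np.array([45.0]))
    assert cd.draws.shape == (small_fit.n_draws, 1)


def test_extrapolation_beyond_basis_domain_raises(small_fit):
    with pytest.raises(ValueError, match="outside"):
        ig.posterior_curve(small_fit, np.array([45.0, 95.0]))


def test_new_athlete_band_is_wider_than_population_band(small_fit):
    grid = np.linspace(10, 80, 20)
    pop = ig.posterior_curve(small_fit, grid)
    new = ig.posterior_curve(small_fit, grid, include_random_variance=True,
                             seed=1)
    lo_p, hi_p = pop.band()
    lo_n, hi_n = new.band()
    assert np.mean(hi_n - lo_n) > np.mean(hi_p - lo_p)


def test_self_ratio_is_identically_one():
    rng = np.random.default_rng(0)
    cd = fake_curve(rng.uniform(50, 150, (200, 91)))
    ratio = ig.functional_ratio(cd, cd)
    np.testing.assert_allclose(ratio.ratio_draws, 1.0)
    lo, hi = ratio.band()
    np.testing.assert_allclose(lo, hi)


def test_scalar_multiple_ratio():
    rng = np.random.default_rng(1)
    den = fake_curve(rng.uniform(50, 150, (100, 91)))
    num = fake_curve(2.0 * den.draws)
    ratio = ig.functional_ratio(num, den)
    np.testing.assert_allclose(ratio.ratio_draws, 2.0)


def test_ratio_scaling_invariance():
    """Scaling all numerator draws by c scales mean and band by c exactly."""
    rng = np.random.default_rng(2)
    num = fake_curve(rng.uniform(80, 120, (150, 91)))
    den = fake_curve(rng.uniform(100, 140, (150, 91)))
    r1 = ig.functional_ratio(num, den)
    r2 = ig.functional_ratio(fake_curve(3.0 * num.draws), den)
    np.testing.assert_allclose(r2.mean, 3.0 * r1.mean)
    for a, b in zip(r2.band(), r1.band()):
        np.testing.assert_allclose(a, 3.0 * b)


def test_mismatched_grids_rejected():
    num = fake_curve(np.ones((10, 91)))
    den = fake_curve(np.ones((10, 46)), grid=np.arange(0, 91, 2.0))
    with pytest.raises(ValueError, match="grid"):
        ig.functional_ratio(num, den)


def test_unequal_draw_counts_subsampled_deterministically():
    rng = np.random.default_rng(3)
    num = fake_curve(rng.uniform(80, 120, (300, 91)))
    den = fake_curve(rng.uniform(100, 140, (200, 91)))
    r1 = ig.functional_ratio(num, den, seed=5)
    r2 = ig.functional_ratio(num, den, seed=5)
    assert r1.ratio_draws.shape == (200, 91)
    np.testing.assert_array_equal(r1.ratio_draws, r2.ratio_draws)


def test_small_denominator_masked_with_warning():
    rng = np.random.default_rng(4)
    num = fake_curve(rng.uniform(80, 120, (50, 91)))
    den_draws = rng.uniform(100, 140, (50, 91))
    den_draws[:, :30] = 0.1     # below the 1 N*m threshold at 30/91 points
    den = fake_curve(den_draws)
    with pytest.warns(UserWarning, match="masked"):
        ratio = ig.functional_ratio(num, den)
    assert ratio.mask.sum() == 30
    assert np.isnan(ratio.mean[:30]).all()
    assert np.isfinite(ratio.mean[30:]).all()


def test_band_endpoints_are_ordered():
    rng = np.random.default_rng(5)
    num = fake_curve(rng.uniform(50, 150, (400, 91)))
    den = fake_curve(rng.uniform(50, 150, (400, 91)))
    r = ig.functional_ratio(num, den)
    lo, hi = r.band()
    med = np.percentile(r.ratio_draws, 50, axis=0)
    assert np.all(lo <= med) and np.all(med <= hi)


def test_linear_crossing_interpolation():
    grid = np.array([0.0, 90.0])
    vals = np.array([1.5, 0.5])
    assert ig.find_level_crossings(grid, vals, 1.0) == [45.0]


def test_no_crossing_returns_empty():
    grid = np.arange(0, 91, 1.0)
    assert ig.find_level_crossings(grid, np.full(91, 0.8), 1.0) == []


def test_cosine_curve_crossings_match_closed_form():
    grid = np.arange(0.0, 91.0, 1.0)
    vals = 1 + 0.3 * np.cos(2 * np.pi * grid / 90)
    crossings = ig.find_level_crossings(grid, vals, 1.0)
    assert len(crossings) == 2
    assert crossings[0] == pytest.approx(22.5, abs=0.5)
    assert crossings[1] == pytest.approx(67.5, abs=0.5)


def test_exact_grid_hit_reported_once():
    grid = np.array([0.0, 1.0, 2.0, 3.0])
    vals = np.array([0.5, 1.0, 1.5, 0.8])
    out = ig.find_level_crossings(grid, vals, 1.0)
    assert out.count(1.0) == 1


@given(st.lists(st.floats(-2, 2), min_size=4, max_size=40), st.floats(-1, 1))
def test_crossings_match_brute_force_bracketing(vals, level):
    """Detector agrees with 0.01-deg brute-force bracketing within one step."""
    vals = np.asarray(vals)
    grid = np.linspace(0, 90, len(vals))
    step = grid[1] - grid[0]
    detected = ig.find_level_crossings(grid, vals, level)
    fine = np.arange(0, 90.0001, 0.01)
    interp = np.interp(fine, grid, vals) - level
    brute = [fine[i] for i in range(len(fine) - 1)
             if interp[i] * interp[i + 1] < 0] \
        + [fine[i] for i in range(len(fine)) if interp[i] == 0]
    for b in brute:
        assert min((abs(b - d) for d in detected), default=np.inf) <= step + 0.011


def test_monotone_curve_has_no_extrema():
    grid = np.arange(0, 91, 1.0)
    assert ig.find_extrema(grid, grid ** 1.5) == []


def test_parabola_peak_detected_at_55():
    grid = np.arange(0.0, 91.0, 1.0)
    vals = -((grid - 55.0) ** 2)
    ext = ig.find_extrema(grid, vals)
    assert ext == [(55.0, 0.0, "max")]


def test_plateau_reports_midpoint():
    grid = np.arange(0.0, 7.0)
    vals = np.array([0.0, 1, 2, 2, 2, 1, 0])
    ext = ig.find_extrema(grid, vals)
    assert len(ext) == 1
    angle, value, kind = ext[0]
    assert (angle, value, kind) == (3.0, 2.0, "max")


def test_masked_stretch_splits_extrema_search():
    grid = np.arange(0.0, 10.0)
    vals = np.array([0.0, 1, 0, np.nan, np.nan, 0, 2, 0, 1, 0])
    ext = ig.find_extrema(grid, vals)
    angles = [a for a, _, _ in ext]
    assert 1.0 in angles and 6.0 in angles
    assert all(np.isfinite(v) for _, v, _ in ext)


def test_waic_zero_variance_single_observation():
    c = -1.7
    ll = np.full((10, 1), c)
    res = ig.compute_waic(ll)
    assert res.p_waic == 0.0
    assert res.waic == pytest.approx(-2 * c)


def test_waic_two_draw_hand_example():
    ll = np.log(np.array([[0.5], [0.25]]))
    res = ig.compute_waic(ll)
    lppd = np.log(0.375)
    p = np.var(ll[:, 0], ddof=1)
    assert res.elpd == pytest.approx(lppd - p, abs=1e-12)
    assert res.waic == pytest.approx(-2 * (lppd - p), abs=1e-12)


def test_waic_single_draw_rejected():
    with pytest.raises(ValueError):
        ig.compute_waic(np.zeros((1, 5)))


def test_waic_matches_straight_loop_oracle(rng):
    import math
    ll = rng.normal(-2.0, 0.7, (50, 5))
    res = ig.compute_waic(ll)
    S, n = ll.shape
    lppd = p_waic = 0.0
    for i in range(n):
        acc = 0.0
        for s in range(S):
            acc += math.exp(ll[s, i])
        lppd += math.log(acc / S)
        mean_l = sum(ll[s, i] for s in range(S)) / S
        p_waic += sum((ll[s, i] - mean_l) ** 2 for s in range(S)) / (S - 1)
    assert res.waic == pytest.approx(-2 * (lppd - p_waic), abs=1e-10)
    assert res.p_waic == pytest.approx(p_waic, abs=1e-10)


def test_waic_agrees_with_arviz():
    """Independent cross-check against the reference implementation."""
    import arviz as az
    rng = np.random.default_rng(9)
    ll = rng.normal(-2.0, 0.5, (1, 400, 8))   # (chain, draw, obs)
    ours = ig.compute_waic(ll[0])
    idata = az.from_dict(log_likelihood={"y": ll})
    ref = az.waic(idata, scale="deviance")
    # arviz estimates p_waic with the population variance (ddof=0) while we
    # use the sample variance; at 400 draws the two agree to ~S^-1
    assert ours.waic == pytest.approx(float(ref.elpd_waic), rel=2e-3)


def test_compare_waic_table_shape(small_fit):
    tab = ig.compare_waic(small_fit, small_fit, names=("a", "b"))
    assert list(tab["model"]) == ["a", "b"]
    assert tab["elpd_diff_vs_other"].iloc[0] == pytest.approx(0.0)


def test_peak_torque_ratio_scalar():
    num = fake_curve(np.full((10, 91), 100.0))
    den = fake_curve(np.full((10, 91), 200.0))
    assert ig.peak_torque_ratio(num, den) == pytest.approx(0.5)
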