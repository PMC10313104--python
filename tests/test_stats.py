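"""Group summaries, per-location Hotelling testing, Bull's eye grids."""

import numpy as np
import pytest
from scipy import stats as sps

from myoatlas.stats import (BullsEye, StatsError, bullseye_summarize,
                            group_average, hotelling_map, hotelling_t2,
                            location_map, plot_bullseye, significant_fraction,
                            transmurality_map, variability_map)


def random_lattices(n, shape=(6, 5, 4), missing=0.1, seed=0):
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        lat = rng.uniform(size=shape)
        lat[rng.uniform(size=shape) < missing] = np.nan
        out.append(lat)
    return out


class TestGroupAverage:
    def test_identical_patterns_have_zero_variability(self):
        lat = random_lattices(1)[0]
        summary = group_average([lat.copy() for _ in range(4)])
        obs = ~np.isnan(summary.mean)
        np.testing.assert_allclose(summary.mean[obs], lat[obs])
        assert np.nanmax(summary.variability) == pytest.approx(0.0)

    def test_two_point_cell(self):
        a = np.zeros((1, 1, 1))
        b = np.ones((1, 1, 1))
        s = group_average([a, b])
        assert s.mean[0, 0, 0] == pytest.approx(0.5)
        assert s.variability[0, 0, 0] == pytest.approx(np.sqrt(0.5), abs=1e-4)

    def test_matches_bruteforce_loops(self):
        pats = random_lattices(50, missing=0.2, seed=3)
        s = group_average(pats, min_coverage=0.0)
        stack = np.stack(pats)
        for idx in [(0, 0, 0), (3, 2, 1), (5, 4, 3)]:
            vals = stack[(slice(None),) + idx]
            vals = vals[~np.isnan(vals)]
            assert s.mean[idx] == pytest.approx(vals.mean(), abs=1e-12)
            assert s.variability[idx] == pytest.approx(vals.std(ddof=1), abs=1e-12)

    def test_majority_missing_cells_flagged(self):
        lat = np.ones((1, 1, 1))
        nanlat = np.full((1, 1, 1), np.nan)
        s = group_average([lat, nanlat, nanlat])     # observed in 1/3 < 50%
        assert np.isnan(s.mean[0, 0, 0])
        s2 = group_average([lat, lat.copy(), nanlat, nanlat])  # exactly 50%
        assert s2.mean[0, 0, 0] == pytest.approx(1.0)

    def test_empty_list_rejected(self):
        with pytest.raises(StatsError):
            group_average([])


class TestLocationTransmurality:
    def test_max_vs_mean_semantics(self):
        lat = np.zeros((2, 1, 5))
        lat[0, 0, :2] = 1.0                      # subendocardial 40% at value 1
        assert location_map(lat)[0, 0] == 1.0
        assert transmurality_map(lat)[0, 0] == pytest.approx(0.4)
        assert location_map(lat)[1, 0] == 0.0    # empty column

    def test_location_dominates_transmurality(self):
        for lat in random_lattices(5, seed=7):
            loc = location_map(lat)
            tm = transmurality_map(lat)
            obs = ~np.isnan(loc)
            assert np.all(loc[obs] >= tm[obs] - 1e-12)

    def test_matches_bruteforce(self):
        lat = random_lattices(1, seed=11)[0]
        loc = location_map(lat)
        tm = transmurality_map(lat)
        for ci in range(lat.shape[0]):
            for zi in range(lat.shape[1]):
                col = lat[ci, zi]
                col = col[~np.isnan(col)]
                if len(col) == 0:
                    assert np.isnan(loc[ci, zi])
                else:
                    assert loc[ci, zi] == pytest.approx(col.max())
                    assert tm[ci, zi] == pytest.approx(col.mean())

    def test_variability_is_sd_of_transmurality(self):
        pats = random_lattices(6, missing=0.0, seed=5)
        vm = variability_map(pats)
        tms = np.stack([transmurality_map(p) for p in pats])
        np.testing.assert_allclose(vm, tms.std(axis=0, ddof=1), atol=1e-12)


class TestHotelling:
    def test_identical_groups_give_p_one(self):
        pats = random_lattices(4, missing=0.0, seed=2)
        pm = hotelling_map(pats, [p.copy() for p in pats])
        assert np.nanmin(pm.p) == pytest.approx(1.0)
        assert np.nanmax(pm.statistic) == pytest.approx(0.0)

    def test_univariate_reduction_equals_t_test(self):
        rng = np.random.default_rng(0)
        for _ in range(30):
            a = rng.normal(size=(7, 1))
            b = rng.normal(0.4, 1.2, size=(9, 1))
            t2, p, q = hotelling_t2(a, b)
            t, pt = sps.ttest_ind(a[:, 0], b[:, 0])
            assert q == 1
            assert t2 == pytest.approx(t ** 2, abs=1e-10)
            assert p == pytest.approx(pt, abs=1e-10)

    def test_symmetric_under_group_exchange(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=(6, 4))
        b = rng.normal(size=(8, 4))
        assert hotelling_t2(a, b)[:2] == pytest.approx(hotelling_t2(b, a)[:2])

    def test_invariant_to_common_shift(self):
        rng = np.random.default_rng(2)
        a = rng.normal(size=(6, 4))
        b = rng.normal(size=(8, 4))
        shift = rng.normal(size=4)
        t2a, pa, _ = hotelling_t2(a, b)
        t2b, pb, _ = hotelling_t2(a + shift, b + shift)
        assert t2a == pytest.approx(t2b, rel=1e-9)
        assert pa == pytest.approx(pb, rel=1e-9)

    def test_rank_deficient_features_handled(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=(10, 2))
        b = rng.normal(0.5, 1, size=(10, 2))
        # duplicate a feature column: covariance rank stays 2
        a3 = np.column_stack([a, a[:, 0]])
        b3 = np.column_stack([b, b[:, 0]])
        t2_full, p_full, q = hotelling_t2(a3, b3)
        t2_red, p_red, _ = hotelling_t2(a, b)
        assert q == 2
        assert t2_full == pytest.approx(t2_red, rel=1e-6)
        assert p_full == pytest.approx(p_red, rel=1e-6)

    def test_agrees_with_permutation_oracle(self):
        # small-scale version of the calibration experiment: batched
        # label-permutation null versus the F-transformed p-value
        rng = np.random.default_rng(42)
        B, npg = 4000, 24
        for _ in range(5):
            X = rng.normal(size=(2 * npg, 3))
            t2_obs, p_f, _ = hotelling_t2(X[:npg], X[npg:])
            t2p = _perm_t2(X, npg, B, rng)
            p_perm = (np.count_nonzero(t2p >= t2_obs - 1e-12) + 1) / (B + 1)
            se = np.sqrt(p_f * (1 - p_f) / B)
            assert abs(p_f - p_perm) <= 3 * se

    def test_min_subjects_per_group_enforced(self):
        pats = random_lattices(4, missing=0.0)
        with pytest.raises(StatsError):
            hotelling_map(pats[:2], pats[2:])

    def test_transmurality_mode_is_univariate(self):
        rng = np.random.default_rng(4)
        ga = random_lattices(6, missing=0.0, seed=10)
        gb = random_lattices(6, missing=0.0, seed=20)
        pm = hotelling_map(ga, gb, mode="transmurality")
        ta = np.stack([transmurality_map(p) for p in ga])
        tb = np.stack([transmurality_map(p) for p in gb])
        ci, zi = 2, 3
        _, p_ref = sps.ttest_ind(ta[:, ci, zi], tb[:, ci, zi])
        assert pm.p[ci, zi] == pytest.approx(p_ref, abs=1e-10)


def _perm_t2(X, na, B, rng):
    """Independent brute-force permutation null of the two-sample T^2."""
    n, d = X.shape
    nb = n - na
    XX = np.einsum("ni,nj->nij", X, X).reshape(n, d * d)
    order = np.argsort(rng.random((B, n)), axis=1)
    G = np.zeros((B, n))
    np.put_along_axis(G, order[:, :na], 1.0, axis=1)
    sumA = G @ X
    sqA = (G @ XX).reshape(-1, d, d)
    sumT = X.sum(0)
    sqT = XX.sum(0).reshape(d, d)
    mA = sumA / na
    mB = (sumT - sumA) / nb
    SA = sqA - na * np.einsum("bi,bj->bij", mA, mA)
    SB = (sqT - sqA) - nb * np.einsum("bi,bj->bij", mB, mB)
    Sp = (SA + SB) / (n - 2)
    diff = mA - mB
    sol = np.linalg.solve(Sp, diff[..., None])[..., 0]
    return na * nb / n * np.einsum("bi,bi->b", diff, sol)


class TestSignificantFraction:
    def test_counting(self):
        p = np.full((8, 6), 0.5)
        p.flat[:12] = 0.01
        pm_like = _pmap(p)
        assert significant_fraction(pm_like) == pytest.approx(100 * 12 / 48)

    def test_all_null_is_zero(self):
        pm_like = _pmap(np.ones((4, 4)))
        assert significant_fraction(pm_like) == 0.0

    def test_all_missing_rejected(self):
        pm_like = _pmap(np.full((4, 4), np.nan))
        with pytest.raises(StatsError):
            significant_fraction(pm_like)


def _pmap(p):
    from myoatlas.stats import PValueMap
    shape = p.shape
    return PValueMap(p=p, statistic=np.zeros(shape),
                     rank=np.ones(shape, dtype=int),
                     n_a=np.full(shape, 5), n_b=np.full(shape, 5))


class TestBullsEye:
    def test_default_layout_21_rings_24_segments(self):
        m = np.zeros((24, 21))
        be = bullseye_summarize(m)
        assert (be.n_rings, be.n_segments) == (21, 24)

    def test_transpose_semantics(self):
        m = np.zeros((24, 21))
        m[5, 13] = 7.0                       # c-bin 5, slice 13
        be = bullseye_summarize(m)
        assert be.values[13, 5] == 7.0       # ring 13, segment 5

    def test_all_missing_stays_missing(self):
        be = bullseye_summarize(np.full((24, 21), np.nan))
        assert np.isnan(be.values).all()

    def test_wedge_cells_counted(self):
        m = np.zeros((24, 21))
        m[0:6, :] = 1.0                      # segments 0-5, all slices
        be = bullseye_summarize(m)
        assert (be.values > 0).sum() == 21 * 6

    def test_shape_mismatch_rejected(self):
        with pytest.raises(StatsError):
            bullseye_summarize(np.zeros((3, 4, 5)))

    def test_plot_renders_log_scale(self, tmp_path):
        import matplotlib
        matplotlib.use("Agg")
        rng = np.random.default_rng(0)
        be = BullsEye(values=rng.uniform(1e-4, 1, size=(21, 24)),
                      metric="p-value", log_scale=True)
        ax = plot_bullseye(be)
        ax.figure.savefig(tmp_path / "be.png")
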