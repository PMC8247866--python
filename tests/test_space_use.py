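from math import erf, sqrt

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as hst

from migvar import space_use as su
from tests.conftest import make_fixes


def _phi(z):
    return 0.5 * (1.0 + erf(z / sqrt(2.0)))


def brute_force_cell_masses(fixes, ud, h):
    """Independent per-cell Gaussian-mixture integral (slow reference)."""
    xe, ye = ud.x_edges(), ud.y_edges()
    m = np.zeros(ud.shape)
    for xi, yi in zip(fixes["x"], fixes["y"]):
        for iy in range(ud.shape[0]):
            for ix in range(ud.shape[1]):
                m[iy, ix] += ((_phi((xe[ix + 1] - xi) / h) - _phi((xe[ix] - xi) / h))
                              * (_phi((ye[iy + 1] - yi) / h) - _phi((ye[iy] - yi) / h)))
    return m / m.sum()


@pytest.fixture(scope="module")
def cluster_ud():
    rng = np.random.default_rng(0)
    xy = np.concatenate([rng.normal(0, 50e3, (120, 2)),
                         rng.normal([600e3, 200e3], 30e3, (80, 2))])
    fx = make_fixes(xy[:, 0], xy[:, 1])
    return su.kde_ud(fx)


class TestKDE:
    def test_normalized(self, cluster_ud):
        assert cluster_ud.masses.sum() == pytest.approx(1.0, abs=1e-9)

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(3)
        xy = rng.normal(0, 80e3, (25, 2))
        fx = make_fixes(xy[:, 0], xy[:, 1])
        ud = su.kde_ud(fx, cell_size=20e3, h=100e3, pad=200e3)
        oracle = brute_force_cell_masses(fx, ud, 100e3)
        assert np.abs(oracle - ud.masses).max() < 1e-10

    def test_point_mass_is_unimodal_and_symmetric(self):
        fx = make_fixes(np.full(10, 5e3), np.full(10, 5e3))
        ud = su.kde_ud(fx, cell_size=10e3, h=100e3)
        iy, ix = np.unravel_index(ud.masses.argmax(), ud.shape)
        cy, cx = ud.cell_index(5e3, 5e3)
        assert (iy, ix) == (cy, cx)
        assert np.allclose(ud.masses, ud.masses[::-1, ::-1].T.T, atol=1e-12)

    def test_two_clusters_mass_split_by_fix_counts(self):
        fx = make_fixes(np.r_[np.zeros(30), np.full(10, 1e6)],
                        np.zeros(40))
        ud = su.kde_ud(fx)
        left = ud.masses[:, ud.x_edges()[:-1] < 5e5].sum()
        assert left == pytest.approx(0.75, abs=1e-6)

    def test_insufficient_fixes(self):
        with pytest.raises(ValueError, match="insufficient"):
            su.kde_ud(make_fixes([0, 1], [0, 1]))

    def test_centre_approximation_close_at_wide_bandwidth(self):
        rng = np.random.default_rng(4)
        xy = rng.normal(0, 50e3, (40, 2))
        fx = make_fixes(xy[:, 0], xy[:, 1])
        exact = su.kde_ud(fx)
        approx = su.kde_ud(fx, cell_mass="centre")
        assert np.abs(exact.masses - approx.masses).max() < 1e-4


class TestIsopleth:
    def test_uniform_tie_broken_row_major(self):
        ud = su.GridUD((0, 0), 1.0, np.full((2, 2), 0.25))
        iso = su.isopleth(ud, 0.5)
        assert iso.member_cells.sum() == 2
        assert iso.member_cells[0].all() and not iso.member_cells[1].any()

    def test_level_one_includes_all_nonzero(self, cluster_ud):
        iso = su.isopleth(cluster_ud, 1.0)
        assert iso.member_cells.sum() == (cluster_ud.masses > 0).sum()

    def test_invalid_level(self, cluster_ud):
        with pytest.raises(ValueError):
            su.isopleth(cluster_ud, 1.5)

    def test_unimodal_50_is_single_component_with_mode(self):
        fx = make_fixes(np.zeros(20), np.zeros(20))
        ud = su.kde_ud(fx)
        iso = su.isopleth(ud, 0.5)
        assert iso.n_components == 1
        iy, ix = np.unravel_index(ud.masses.argmax(), ud.shape)
        assert iso.member_cells[iy, ix]


class TestBhattacharyya:
    def test_hand_value(self):
        u1 = su.GridUD((0, 0), 1.0, np.array([[0.5, 0.5]]))
        u2 = su.GridUD((0, 0), 1.0, np.array([[1.0, 0.0]]))
        assert su.bhattacharyya(u1, u2) == pytest.approx(np.sqrt(0.5))

    def test_disjoint_supports_zero(self):
        u1 = su.GridUD((0, 0), 1.0, np.array([[1.0, 0.0]]))
        u2 = su.GridUD((0, 0), 1.0, np.array([[0.0, 1.0]]))
        assert su.bhattacharyya(u1, u2) == 0.0

    def test_truncated_self_overlap_is_095(self, cluster_ud):
        tr = su.truncate_ud(cluster_ud, 0.95)
        assert su.bhattacharyya(tr, tr) == pytest.approx(0.95, abs=0.002)
        assert su.bhattacharyya(cluster_ud, cluster_ud) == pytest.approx(1.0, abs=1e-9)

    def test_mismatched_grids_raise(self, cluster_ud):
        other = su.GridUD((0, 0), 1.0, np.array([[1.0]]))
        with pytest.raises(su.GridMismatchError):
            su.bhattacharyya(cluster_ud, other)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(hst.integers(0, 2**31 - 1))
    def test_symmetry_and_bounds_property(self, seed):
        rng = np.random.default_rng(seed)
        m1 = rng.random((4, 5)); m1 /= m1.sum()
        m2 = rng.random((4, 5)); m2 /= m2.sum()
        u1 = su.GridUD((0, 0), 1.0, m1)
        u2 = su.GridUD((0, 0), 1.0, m2)
        ba = su.bhattacharyya(u1, u2)
        assert 0.0 <= ba <= 1.0 + 1e-12
        assert ba == pytest.approx(su.bhattacharyya(u2, u1), abs=1e-12)


class TestDiffusion:
    def test_brownian_recovery_within_20_percent(self):
        rng = np.random.default_rng(2)
        D, dt, n = 5.0, 600.0, 1000
        xy = np.cumsum(rng.normal(0, np.sqrt(2 * D * dt), (n, 2)), axis=0)
        fx = make_fixes(xy[:, 0], xy[:, 1], freq="10min")
        assert su.estimate_diffusion(fx) == pytest.approx(D, rel=0.2)

    def test_short_steps_rejected(self):
        fx = make_fixes(np.zeros(20), np.zeros(20))
        with pytest.raises(ValueError, match="eligible"):
            su.estimate_diffusion(fx)

    def test_doubling_lengths_quadruples_d(self):
        rng = np.random.default_rng(9)
        xy = np.cumsum(rng.normal(0, 120, (200, 2)), axis=0)
        fx1 = make_fixes(xy[:, 0], xy[:, 1], freq="10min")
        fx2 = make_fixes(2 * xy[:, 0], 2 * xy[:, 1], freq="10min")
        p = su.BRBParams(l_min_m=1e-9)  # same eligible set at both scales
        assert su.estimate_diffusion(fx2, p) == pytest.approx(
            4 * su.estimate_diffusion(fx1, p), rel=1e-9)


class TestBRB:
    def test_stationary_equals_minimum_kernel(self):
        fx = make_fixes(np.zeros(50), np.zeros(50))
        params = su.BRBParams(diffusion_m2s=0.0)
        b = su.brb_ud(fx, cell_size=100.0, params=params, pad=600.0)
        k = su.kde_ud(fx, cell_size=100.0, h=150.0, pad=600.0)
        assert b.origin == k.origin and b.shape == k.shape
        assert np.abs(b.masses - k.masses).max() < 1e-6

    def test_ridge_mass_exceeds_offset_mass(self):
        fx = make_fixes([0.0, 2000.0], [0.0, 0.0], freq="2h")
        b = su.brb_ud(fx, cell_size=100.0,
                      params=su.BRBParams(diffusion_m2s=0.05), pad=1500.0)
        on = b.masses[b.cell_index(1000.0, 0.0)]
        off = b.masses[b.cell_index(1000.0, 1200.0)]
        assert on > off
        assert b.masses.sum() == pytest.approx(1.0, abs=1e-9)

    def test_long_gap_contributes_endpoint_kernels_only(self):
        ts = pd.to_datetime(["2020-01-01T00:00", "2020-01-01T12:00"], utc=True)
        fx = pd.DataFrame({"timestamp": ts, "x": [0.0, 5000.0], "y": [0.0, 0.0]})
        b = su.brb_ud(fx, cell_size=100.0,
                      params=su.BRBParams(diffusion_m2s=0.05), pad=800.0)
        mid = b.masses[b.cell_index(2500.0, 0.0)]
        end = b.masses[b.cell_index(0.0, 0.0)]
        assert end > 100 * max(mid, 1e-30)

    def test_empty_window_raises(self):
        with pytest.raises(ValueError, match="empty"):
            su.brb_ud(make_fixes([], []))


class TestOverlapAggregates:
    def test_identical_seasons_095(self, cluster_ud):
        mean_ba, pairs = su.seasonal_overlap_matrix([cluster_ud, cluster_ud])
        assert mean_ba == pytest.approx(0.95, abs=0.002)
        assert len(pairs) == 1

    def test_three_seasons_three_pairs_mean_between_extremes(self):
        rng = np.random.default_rng(1)
        uds = []
        for shift in (0.0, 0.0, 400e3):  # one divergent year
            xy = rng.normal([shift, 0], 40e3, (60, 2))
            uds.append(su.kde_ud(make_fixes(xy[:, 0], xy[:, 1])))
        mean_ba, pairs = su.seasonal_overlap_matrix(uds)
        vals = list(pairs.values())
        assert len(vals) == 3
        assert min(vals) < mean_ba < max(vals)

    def test_distant_winters_fidelity_zero(self):
        rng = np.random.default_rng(6)
        a = rng.normal(0, 500, (80, 2))
        b = rng.normal(50e3, 500, (80, 2))
        u1 = su.brb_ud(make_fixes(a[:, 0], a[:, 1]), cell_size=500.0,
                       params=su.BRBParams(diffusion_m2s=0.1))
        u2 = su.brb_ud(make_fixes(b[:, 0], b[:, 1]), cell_size=500.0,
                       params=su.BRBParams(diffusion_m2s=0.1))
        fid, _ = su.winter_site_fidelity([u1, u2])
        assert fid == pytest.approx(0.0, abs=1e-9)

    def test_ba_equals_bruteforce_cell_sum(self):
        rng = np.random.default_rng(7)
        a = rng.normal(0, 2e3, (50, 2))
        b = np.concatenate([rng.normal(0, 2e3, (25, 2)),
                            rng.normal(8e3, 2e3, (25, 2))])  # shares one roost
        u1 = su.brb_ud(make_fixes(a[:, 0], a[:, 1]), cell_size=500.0,
                       params=su.BRBParams(diffusion_m2s=0.5))
        u2 = su.brb_ud(make_fixes(b[:, 0], b[:, 1]), cell_size=500.0,
                       params=su.BRBParams(diffusion_m2s=0.5))
        g1, g2 = su.common_grid([u1, u2])
        t1, t2 = su.truncate_ud(g1, 0.95), su.truncate_ud(g2, 0.95)
        ba = su.bhattacharyya(t1, t2)
        manual = sum(sqrt(p * q) for p, q in
                     zip(t1.masses.ravel(), t2.masses.ravel()) if p > 0 and q > 0)
        assert ba == pytest.approx(manual, abs=1e-12)
        assert 0.0 < ba < 0.95


def test_esri_ascii_roundtrip(tmp_path, cluster_ud):
    path = tmp_path / "ud.asc"
    su.write_esri_ascii(cluster_ud, path)
    lines = path.read_text().splitlines()
    assert lines[0].startswith("ncols")
    grid = np.loadtxt(lines[6:])[::-1]
    assert np.abs(grid - cluster_ud.masses).max() < 1e-9


def test_isopleth_geojson_export(cluster_ud):
    iso = su.isopleth(cluster_ud, 0.5)
    gj = su.isopleths_to_geojson(iso, properties={"role": "core"})
    assert gj["type"] == "FeatureCollection"
    assert len(gj["features"]) == iso.n_components
    assert gj["features"][0]["properties"]["role"] == "core"
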