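"""Second-order statistics: K/L estimators, envelopes, classification, d_cut."""

import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

import standstruct as st
from standstruct import PatternError, PlotWindow
from standstruct.secondorder import _isotropic_weight

from conftest import make_pattern


def brute_force_k(xy, area, grid):
    """O(n^2) uncorrected K: (A/n^2) * #{ordered pairs with d < r}."""
    n = len(xy)
    out = np.zeros(len(grid))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            d = np.hypot(*(xy[i] - xy[j]))
            out += (d < grid)
    return area / n**2 * out


class TestUnivariateK:

    def test_grid_validation(self, window):
        with pytest.raises(PatternError):
            st.distance_grid(r_max=30, window=window)  # > half shorter side
        with pytest.raises(PatternError):
            st.distance_grid(step=-1)

    def test_two_points_hand_count(self):
        p = make_pattern([25, 26], [25, 25])   # 1 m apart, A = 2500
        res = st.ripley_k_univariate(p, np.array([0.5, 2.0]), "none")
        assert res.values[0] == 0.0
        assert res.values[1] == pytest.approx(2500 / 4 * 2)   # 1250

    def test_equals_bruteforce_without_correction(self, window):
        rng = np.random.default_rng(17)
        xy = rng.uniform(0, 50, size=(120, 2))
        p = make_pattern(xy[:, 0], xy[:, 1], window=window)
        grid = st.distance_grid()
        res = st.ripley_k_univariate(p, grid, "none")
        np.testing.assert_allclose(res.values,
                                   brute_force_k(xy, 2500, grid), atol=1e-12)

    def test_interior_cluster_needs_no_correction(self):
        # all pairs far from edges: every isotropic weight is exactly 1
        rng = np.random.default_rng(4)
        xy = rng.uniform(22, 28, size=(30, 2))
        p = make_pattern(xy[:, 0], xy[:, 1])
        grid = np.arange(0.25, 10.01, 0.25)
        iso = st.ripley_k_univariate(p, grid, "isotropic").values
        unc = st.ripley_k_univariate(p, grid, "none").values
        np.testing.assert_allclose(iso, unc, atol=1e-12)

    def test_isotropic_weight_exact_edge_case(self):
        # point 1 m from one edge, circle of radius 2: the arc beyond that
        # edge subtends 2*arccos(1/2); weight = 1/(1 - arc/2pi)
        w = _isotropic_weight(np.array([[1.0, 25.0]]), np.array([2.0]),
                              PlotWindow())
        arc = 2 * np.arccos(0.5)
        assert w[0] == pytest.approx(1 / (1 - arc / (2 * np.pi)), rel=1e-12)


class TestLTransform:

    def test_hand_values(self):
        grid = np.array([1.0, 2.0])
        res = st.SecondOrderResult("K_U", grid, np.pi * grid**2, "none", n=10)
        np.testing.assert_allclose(st.l_univariate(res).values, 0, atol=1e-12)
        res2 = st.SecondOrderResult("K_U", np.array([1.0]),
                                    np.array([2 * np.pi]), "none", n=10)
        assert st.l_univariate(res2).values[0] == pytest.approx(
            np.sqrt(2) - 1, abs=1e-4)
        res3 = st.SecondOrderResult("K_U", np.array([1.0]), np.array([0.0]),
                                    "none", n=10)
        assert st.l_univariate(res3).values[0] == -1.0

    def test_negative_k_rejected(self):
        res = st.SecondOrderResult("K_U", np.array([1.0]), np.array([-1.0]),
                                   "none", n=10)
        with pytest.raises(PatternError):
            st.l_univariate(res)

    def test_monotone_in_k(self):
        grid = np.array([1.0, 3.0, 5.0])
        lo = st.l_univariate(st.SecondOrderResult("K_U", grid, grid**2,
                                                  "none", n=5)).values
        hi = st.l_univariate(st.SecondOrderResult("K_U", grid, 2 * grid**2,
                                                  "none", n=5)).values
        assert (hi > lo).all()


class TestBivariateK:

    def _two_type_pattern(self, seed=21, n_a=25, n_b=15):
        rng = np.random.default_rng(seed)
        xy = rng.uniform(0, 50, size=(n_a + n_b, 2))
        species = ["a"] * n_a + ["b"] * n_b
        return make_pattern(xy[:, 0], xy[:, 1], species=species), xy

    def test_equal_counts_give_plain_mean(self):
        p, _ = self._two_type_pattern(n_a=15, n_b=15)
        res = st.ripley_k_bivariate(p, "a", "b", np.array([3.0, 6.0]), "none")
        np.testing.assert_allclose(res.values, (res.k_ij + res.k_ji) / 2)

    def test_weighted_recombination_identity(self):
        p, _ = self._two_type_pattern()
        res = st.ripley_k_bivariate(p, "a", "b", correction="isotropic")
        recomb = (res.n_i * res.k_ij + res.n_j * res.k_ji) / (res.n_i + res.n_j)
        np.testing.assert_allclose(res.values, recomb, atol=1e-12)

    def test_cross_pairs_match_bruteforce(self):
        p, xy = self._two_type_pattern(n_a=10, n_b=10)
        grid = st.distance_grid()
        res = st.ripley_k_bivariate(p, "a", "b", grid, "none")
        counts = np.zeros(len(grid))
        for i in range(10):
            for j in range(10, 20):
                counts += np.hypot(*(xy[i] - xy[j])) < grid
        np.testing.assert_allclose(res.k_ij, 2500 / 100 * counts, atol=1e-12)

    def test_absent_or_overlapping_types_rejected(self):
        p, _ = self._two_type_pattern()
        with pytest.raises(PatternError, match="type_j"):
            st.ripley_k_bivariate(p, "a", "zz")
        with pytest.raises(PatternError, match="disjoint"):
            st.ripley_k_bivariate(p, "a", "a")

    def test_l_bivariate_hand_values(self):
        res = st.SecondOrderResult("K_B", np.array([1.0]),
                                   np.array([4 * np.pi]), "none", n_i=3, n_j=3)
        assert st.l_bivariate(res).values[0] == pytest.approx(1.0)
        res0 = st.SecondOrderResult("K_B", np.array([2.0]), np.array([0.0]),
                                    "none", n_i=3, n_j=3)
        assert st.l_bivariate(res0).values[0] == -2.0


@pytest.mark.skipif(shutil.which("Rscript") is None,
                    reason="Rscript not on PATH")
class TestAgainstSpatstat:
    """Independent oracle: spatstat's Kest/Kcross on a fixed small pattern.

    spatstat normalises by the unbiased intensity-square estimator
    n(n-1)/A^2 where this package follows the plain A/n^2 definition, so the
    univariate comparison rescales by n/(n-1).
    """

    def test_isotropic_translation_and_cross(self, tmp_path):
        rng = np.random.default_rng(42)
        n = 40
        xy = rng.uniform(0, 50, size=(n, 2))
        marks = np.repeat(["a", "b"], [25, 15])
        df = pd.DataFrame({"x": xy[:, 0], "y": xy[:, 1], "m": marks})
        df.to_csv(tmp_path / "pts.csv", index=False)
        script = textwrap.dedent(f"""
            suppressMessages({{library(spatstat.geom); library(spatstat.explore)}})
            d <- read.csv("{tmp_path / 'pts.csv'}")
            pp <- ppp(d$x, d$y, window=owin(c(0,50), c(0,50)),
                      marks=factor(d$m))
            r <- seq(0, 12, by=0.25)
            k <- Kest(unmark(pp), r=r, correction=c("isotropic","translate"))
            kc <- Kcross(pp, "a", "b", r=r, correction="isotropic")
            write.csv(data.frame(r=k$r, iso=k$iso, trans=k$trans, cross=kc$iso),
                      "{tmp_path / 'kest.csv'}", row.names=FALSE)
        """)
        subprocess.run(["Rscript", "-e", script], check=True,
                       capture_output=True)
        ref = pd.read_csv(tmp_path / "kest.csv").iloc[1:]   # drop r = 0
        p = make_pattern(xy[:, 0], xy[:, 1], species=marks)
        grid = st.distance_grid()
        for corr, col in (("isotropic", "iso"), ("translation", "trans")):
            mine = st.ripley_k_univariate(p, grid, corr).values * n / (n - 1)
            np.testing.assert_allclose(mine, ref[col].to_numpy(), atol=1e-8)
        kb = st.ripley_k_bivariate(p, "a", "b", grid, "isotropic")
        np.testing.assert_allclose(kb.k_ij, ref["cross"].to_numpy(), atol=1e-8)


class TestEnvelopes:

    def test_csr_envelope_contains_zero(self, csr_pattern):
        env = st.csr_envelope(csr_pattern, n_sim=199, seed=1)
        assert (env.lower <= 0).all() and (env.upper >= 0).all()

    def test_csr_observation_mostly_inside(self):
        ok = 0
        for seed in range(3):
            p = st.gen_csr(60, seed=seed)
            grid = st.distance_grid()
            l_obs = st.l_univariate(st.ripley_k_univariate(p, grid))
            env = st.csr_envelope(p, grid, n_sim=199, seed=seed + 50)
            inside = (l_obs.values >= env.lower) & (l_obs.values <= env.upper)
            ok += inside.mean() >= 0.95
        assert ok >= 2

    def test_thomas_exceeds_upper_bound_at_small_r(self):
        p = st.gen_thomas(20, 8, 1.0, seed=3)
        grid = st.distance_grid()
        l_obs = st.l_univariate(st.ripley_k_univariate(p, grid))
        env = st.csr_envelope(p, grid, n_sim=199, seed=7)
        small = grid <= 3.0
        assert (l_obs.values[small] > env.upper[small]).any()

    def test_envelope_width_monotone_in_level(self, csr_pattern):
        # at fixed n_sim a wider nominal level uses more extreme ranks
        e95 = st.csr_envelope(csr_pattern, n_sim=199, level=0.95, seed=5)
        e99 = st.csr_envelope(csr_pattern, n_sim=199, level=0.99, seed=5)
        assert (e99.upper >= e95.upper).all()
        assert (e99.lower <= e95.lower).all()
        assert (e99.upper - e99.lower).mean() > (e95.upper - e95.lower).mean()

    def test_independence_envelope_null_and_shared_clusters(self):
        rng = np.random.default_rng(31)
        # independent CSR types: observation inside at nearly all distances
        a = rng.uniform(0, 50, size=(40, 2))
        b = rng.uniform(0, 50, size=(30, 2))
        p = make_pattern(np.r_[a[:, 0], b[:, 0]], np.r_[a[:, 1], b[:, 1]],
                         species=["a"] * 40 + ["b"] * 30)
        grid = st.distance_grid()
        l_obs = st.l_bivariate(st.ripley_k_bivariate(p, "a", "b", grid))
        env = st.independence_envelope(p, "a", "b", grid, n_sim=199, seed=9)
        inside = (l_obs.values >= env.lower) & (l_obs.values <= env.upper)
        assert inside.mean() >= 0.9

        # both types offspring of the same parents: aggregated at small r
        parents = rng.uniform(5, 45, size=(8, 2))
        off = lambda m: (parents[rng.integers(0, 8, m)]
                         + rng.normal(0, 1.0, size=(m, 2)))
        a2, b2 = off(40), off(30)
        p2 = make_pattern(np.r_[a2[:, 0], b2[:, 0]], np.r_[a2[:, 1], b2[:, 1]],
                          species=["a"] * 40 + ["b"] * 30)
        l2 = st.l_bivariate(st.ripley_k_bivariate(p2, "a", "b", grid))
        env2 = st.independence_envelope(p2, "a", "b", grid, n_sim=199, seed=10)
        small = grid <= 3.0
        assert (l2.values[small] > env2.upper[small]).any()

    def test_single_point_type_warns(self):
        p = make_pattern([10, 20, 30, 40], [10, 20, 30, 40],
                         species=["a", "a", "a", "b"])
        with pytest.warns(UserWarning, match="degenerate"):
            st.independence_envelope(p, "a", "b", n_sim=20, seed=1)


class TestClassifyScales:

    def _mk(self, values, lo=-1.0, hi=1.0):
        grid = np.arange(0.5, 10.01, 0.5)
        l_res = st.SecondOrderResult("L_U", grid, np.asarray(values), "none",
                                     n=10)
        env = st.Envelope(grid, np.full_like(grid, lo), np.full_like(grid, hi),
                          99, 0.99, "CSR")
        return l_res, env

    def test_inside_everywhere(self):
        l_res, env = self._mk(np.zeros(20))
        assert st.classify_scales(l_res, env).verdict == "CSR"
        assert st.classify_scales(l_res, env, "bivariate").verdict == \
            "Independence"

    def test_above_run_reported_with_bounds(self):
        vals = np.zeros(20)
        vals[3:16] = 2.0          # r = 2.0 ... 8.0
        l_res, env = self._mk(vals)
        c = st.classify_scales(l_res, env)
        assert c.verdict == "clustering at 2 <= r <= 8 m"
        assert (c.labels == "above").sum() == 13

    def test_single_point_excursion_and_below(self):
        vals = np.zeros(20)
        vals[0] = -5.0
        l_res, env = self._mk(vals)
        assert st.classify_scales(l_res, env).verdict == \
            "regularity at r = 0.5 m"
        assert st.classify_scales(l_res, env, "bivariate").verdict == \
            "repulsion at r = 0.5 m"

    def test_shift_inside_band_is_invariant(self):
        vals = np.zeros(20)
        l_res, env = self._mk(vals)
        shifted, _ = self._mk(vals + 0.5)
        assert st.classify_scales(l_res, env).verdict == \
            st.classify_scales(shifted, env).verdict

    def test_grid_mismatch_rejected(self):
        l_res, env = self._mk(np.zeros(20))
        bad = st.Envelope(l_res.grid[:-1], env.lower[:-1], env.upper[:-1],
                          99, 0.99, "CSR")
        with pytest.raises(PatternError, match="grid"):
            st.classify_scales(l_res, bad)


class TestDCutScan:

    def test_recovers_planted_threshold(self):
        spec = st.StandSpec(n_trees=240, size_link=(25.0, 2.0), seed=100,
                            dbh_rate=0.05)
        p = st.gen_marked_stand(spec)
        scan = st.dcut_scan(p, step=1.0, n_sim=99, seed=5)
        assert scan.significant
        assert abs(scan.chosen - 25.0) <= 3.0

    def test_independent_marks_score_near_zero(self):
        spec = st.StandSpec(n_trees=240, seed=101, dbh_rate=0.05)
        p = st.gen_marked_stand(spec)
        scan = st.dcut_scan(p, step=2.0, n_sim=99, seed=6)
        assert np.nanmax(scan.scores) < 0.3

    def test_degenerate_marks_fail(self):
        p = make_pattern([10, 20, 30], [10, 20, 30], dbh=[20, 20, 20])
        with pytest.raises(PatternError, match="non-empty"):
            st.dcut_scan(p, n_sim=20)
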