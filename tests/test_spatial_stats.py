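"""Moran scatter, DSPAC, LMIC and the conditional-permutation test."""

import math

import numpy as np
import pytest
from scipy import stats

from spatcons.spatial_stats import (
    DspacResult,
    dspac,
    dspac_no_correlation_test,
    lmic,
    lmic_mc_test,
    moran_scatter,
    neighbor_average,
)
from spatcons.structure_graph import NeighborhoodSpec, neighborhoods

from tests.conftest import graph_from_coords, random_geometric_graph, scores_for

BIG = NeighborhoodSpec(D=1000.0, max_separation=3)


def brute_force_lmic(graph, scores, spec):
    """Direct evaluation of the local statistic from its definition."""
    ids = [nid for nid in graph.surface_ids if nid in scores.values]
    y = np.array([scores.values[i] for i in ids])
    ybar, sigma = y.mean(), y.std()
    nb = neighborhoods(graph, spec)
    out = {}
    for k, i in enumerate(ids):
        s = sum(scores.values[j] - ybar for j in nb[i] if j in scores.values)
        out[i] = (y[k] - ybar) * s / sigma**2
    return out


class TestNeighborAverage:
    def test_constant_scores_center_to_zero(self, line_graph):
        s = scores_for(line_graph, [0.4] * 5)
        for nid in line_graph.surface_ids:
            a = neighbor_average(s, line_graph, BIG, nid)
            assert a == pytest.approx(0.0, abs=1e-15) or math.isnan(a)

    def test_balanced_neighbors_cancel(self):
        g = graph_from_coords(
            [(0, 0, 0), (1, 0, 0), (-1, 0, 0)], edges=[(0, 1), (0, 2)]
        )
        # center 0.5, neighbors 1.0 and 0.0 -> centered +-0.5 -> average 0
        s = scores_for(g, [0.5, 1.0, 0.0])
        assert neighbor_average(s, g, BIG, "A:1") == pytest.approx(0.0, abs=1e-15)

    def test_path_center_brute_force(self, line_graph):
        # scores (0,0,1,0,0); N(center) at D=1000, sep<=3 is all 4 others;
        # ybar=0.2: A = ((0-.2)*4)/4 = -0.2
        s = scores_for(line_graph, [0, 0, 1, 0, 0])
        assert neighbor_average(s, line_graph, BIG, "A:3") == pytest.approx(-0.2)

    def test_no_neighbors_yields_nan(self):
        g = graph_from_coords([(0, 0, 0), (1, 0, 0), (50, 0, 0)], edges=[(0, 1)])
        s = scores_for(g, [0.1, 0.9, 0.5])
        assert math.isnan(neighbor_average(s, g, NeighborhoodSpec(D=5.0), "A:3"))


class TestDspac:
    def test_two_segregated_blocks_give_unit_correlation(self):
        # two 4-cliques far apart, one high one low, no cross edges
        coords = [(k, 0, 0) for k in range(4)] + [(k, 100, 0) for k in range(4)]
        edges = [(a, b) for a in range(4) for b in range(a + 1, 4)]
        edges += [(a + 4, b + 4) for a in range(4) for b in range(a + 1, 4)]
        g = graph_from_coords(coords, edges)
        s = scores_for(g, [0.9] * 4 + [0.1] * 4)
        r = dspac(s, g, NeighborhoodSpec(D=10.0)).dspac
        assert r == pytest.approx(1.0, abs=1e-9)

    def test_checkerboard_ring_is_negative(self):
        n = 12
        coords = [
            (10 * np.cos(2 * np.pi * k / n), 10 * np.sin(2 * np.pi * k / n), 0)
            for k in range(n)
        ]
        edges = [(k, (k + 1) % n) for k in range(n)]
        g = graph_from_coords(coords, edges)
        s = scores_for(g, [0.9 if k % 2 else 0.1 for k in range(n)])
        res = dspac(s, g, NeighborhoodSpec(D=6.0))
        # direct Pearson on the construction
        sc = moran_scatter(s, g, NeighborhoodSpec(D=6.0))
        assert res.dspac == pytest.approx(float(np.corrcoef(sc.x, sc.a)[0, 1]))
        assert res.dspac < 0

    def test_null_attributes_rarely_correlate(self):
        g = random_geometric_graph(100, radius=18.0, box=100.0, seed=3)
        rng = np.random.default_rng(42)
        spec = NeighborhoodSpec(D=18.0)
        hits = 0
        n_rep = 200
        for _ in range(n_rep):
            s = scores_for(g, rng.uniform(size=100))
            r = dspac(s, g, spec).dspac
            if abs(r) < 0.3:
                hits += 1
        assert hits >= 0.95 * n_rep

    def test_affine_rescaling_invariance(self, line_graph):
        rng = np.random.default_rng(1)
        y = rng.uniform(size=5)
        spec = NeighborhoodSpec(D=2.2)
        base = dspac(scores_for(line_graph, y), line_graph, spec).dspac
        scaled = dspac(
            scores_for(line_graph, 3.7 * y + 0.21), line_graph, spec
        ).dspac
        assert scaled == pytest.approx(base, abs=1e-12)

    def test_degenerate_scatter_reported_not_raised(self, line_graph):
        s = scores_for(line_graph, [0.5] * 5)
        res = dspac(s, line_graph, BIG)
        assert res.degenerate


class TestNoCorrelationTest:
    def test_zero_correlation_p_is_one(self):
        res = DspacResult(dspac=0.0, slope=0.0, n_points=30, p_value=1.0)
        assert dspac_no_correlation_test(res) == pytest.approx(1.0)

    def test_monotone_in_r(self):
        ps = [
            dspac_no_correlation_test(
                DspacResult(dspac=r, slope=r, n_points=50, p_value=1)
            )
            for r in (0.1, 0.3, 0.5, 0.7, 0.9)
        ]
        assert all(a > b for a, b in zip(ps, ps[1:]))

    def test_typical_protein_magnitude_is_significant(self):
        res = DspacResult(dspac=0.741, slope=0.7, n_points=100, p_value=1)
        assert dspac_no_correlation_test(res) < 0.05

    def test_perfect_correlation_smallest_positive(self):
        res = DspacResult(dspac=1.0, slope=1.0, n_points=10, p_value=1)
        p = dspac_no_correlation_test(res)
        assert 0 < p <= np.nextafter(0.0, 1.0)

    def test_matches_scipy_pearsonr_p(self):
        g = random_geometric_graph(60, radius=20.0, box=80.0, seed=9)
        rng = np.random.default_rng(2)
        s = scores_for(g, rng.uniform(size=60))
        spec = NeighborhoodSpec(D=20.0)
        res = dspac(s, g, spec)
        sc = moran_scatter(s, g, spec)
        r, p = stats.pearsonr(sc.x, sc.a)
        assert res.dspac == pytest.approx(float(r), abs=1e-12)
        assert res.p_value == pytest.approx(float(p), rel=1e-9)


class TestLmic:
    def test_mean_valued_residue_scores_zero(self, line_graph):
        s = scores_for(line_graph, [0.2, 0.4, 0.3, 0.1, 0.5])
        # residue 3 sits exactly at the mean
        res = lmic(s, line_graph, BIG)
        assert res.values["A:3"] == pytest.approx(0.0, abs=1e-12)

    def test_sign_structure(self):
        # star center with 3 leaves, plus a detached node anchoring the mean
        star = graph_from_coords(
            [(0, 0, 0), (1, 0, 0), (-1, 0, 0), (0, 1, 0), (50, 50, 50)],
            edges=[(0, 1), (0, 2), (0, 3)],
        )
        high_near_high = scores_for(star, [0.9, 0.9, 0.9, 0.9, 0.1])
        assert lmic(high_near_high, star, BIG).values["A:1"] > 0
        high_near_low = scores_for(star, [0.9, 0.1, 0.1, 0.1, 0.9])
        assert lmic(high_near_low, star, BIG).values["A:1"] < 0

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_small_instances(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 13))
        g = random_geometric_graph(n, radius=30.0, box=40.0, seed=seed + 10)
        s = scores_for(g, rng.uniform(size=n))
        spec = NeighborhoodSpec(D=25.0, max_separation=2)
        got = lmic(s, g, spec).values
        expected = brute_force_lmic(g, s, spec)
        for nid in got:
            assert got[nid] == pytest.approx(expected[nid], abs=1e-12)

    def test_constant_field_rejected(self, line_graph):
        with pytest.raises(ValueError, match="constant conservation"):
            lmic(scores_for(line_graph, [0.3] * 5), line_graph, BIG)


class TestMcTest:
    def test_constant_conservation_nothing_significant(self, line_graph):
        s = scores_for(line_graph, [0.3] * 5)
        res = lmic_mc_test(s, line_graph, BIG, n_perm=200, seed=0)
        assert res.significant_ids == set()

    def test_deterministic_and_counts_replicates(self):
        g = random_geometric_graph(30, radius=15.0, box=40.0, seed=4)
        rng = np.random.default_rng(8)
        s = scores_for(g, rng.uniform(size=30))
        spec = NeighborhoodSpec(D=15.0)
        a = lmic_mc_test(s, g, spec, n_perm=300, seed=123)
        b = lmic_mc_test(s, g, spec, n_perm=300, seed=123)
        assert a.significant == b.significant
        assert a.thresholds == b.thresholds
        assert a.p_values == b.p_values
        assert set(a.perm_counts.values()) == {300}

    def test_too_few_replicates_rejected(self, line_graph):
        s = scores_for(line_graph, [0.1, 0.2, 0.9, 0.2, 0.1])
        with pytest.raises(ValueError, match="too few replicates"):
            lmic_mc_test(s, line_graph, BIG, n_perm=50, seed=0)

    def test_planted_patch_detected_background_clean(self):
        from spatcons.config import RunConfig
        from spatcons.pipeline import build_graph
        from spatcons.simulate import make_toy_structure

        s_toy = make_toy_structure("sphere", 150, 8, seed=21)
        graph = build_graph(s_toy.pdb_text, "A", RunConfig())
        rng = np.random.default_rng(22)
        values = dict(zip(graph.surface_ids, rng.uniform(0.1, 0.4, size=150)))
        for nid in s_toy.patch:
            values[nid] = 0.95
        from spatcons.conservation import ResidueScores

        scores = ResidueScores(values=values)
        spec = NeighborhoodSpec(D=6.0)
        res = lmic_mc_test(scores, graph, spec, n_perm=1000, seed=5)
        patch = set(s_toy.patch)
        flagged = res.significant_ids
        assert len(flagged & patch) >= 6
        background = set(graph.surface_ids) - patch
        assert len(flagged & background) <= 0.05 * len(background)

    def test_alpha_one_flags_every_above_mean_residue(self):
        g = random_geometric_graph(25, radius=15.0, box=30.0, seed=6)
        rng = np.random.default_rng(7)
        s = scores_for(g, rng.uniform(size=25))
        spec = NeighborhoodSpec(D=15.0)
        res = lmic_mc_test(s, g, spec, n_perm=200, alpha_fraction=1.0, seed=1)
        nb = neighborhoods(g, spec)
        mean = np.mean(list(s.values.values()))
        expected = {
            nid
            for nid in g.surface_ids
            if s.values[nid] > mean and nb[nid]
            and res.lmic.values[nid] > res.thresholds[nid]
        }
        # threshold is the minimum permuted value; observed exceeds it for
        # essentially every above-mean residue with a neighbourhood
        above = {nid for nid in g.surface_ids if s.values[nid] > mean and nb[nid]}
        assert res.significant_ids == expected
        assert len(expected) >= 0.8 * len(above)

    def test_pvalues_uniform_under_exchangeability(self):
        g = random_geometric_graph(120, radius=16.0, box=60.0, seed=14)
        rng = np.random.default_rng(15)
        s = scores_for(g, rng.uniform(size=120))
        spec = NeighborhoodSpec(D=16.0)
        res = lmic_mc_test(s, g, spec, n_perm=1000, seed=16)
        nb = neighborhoods(g, spec)
        ps = [res.p_values[nid] for nid in g.surface_ids if nb[nid]]
        d = stats.kstest(ps, "uniform").statistic
        assert d < 0.12
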