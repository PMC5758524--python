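from itertools import combinations

import numpy as np
import pytest
from scipy.stats import hypergeom

from mutualnet import (
    build_network,
    ce_probabilities,
    dm_null_test,
    randomize_degree_preserving,
    randomize_fill_preserving,
    sample_ce,
)
from mutualnet.core import LayerMatrix


def _layer(presence, kind="pollination"):
    presence = np.asarray(presence)
    m, n = presence.shape
    return LayerMatrix(
        kind, [f"p{i}" for i in range(m)], [f"b{j}" for j in range(n)], presence
    )


def exact_dm_p(m, n, ka, kb, observed):
    """Enumerate all joint placements of both layers; exact P(DM >= obs).

    Independent uniform placements of ka and kb links in m*n cells; the
    coincidence count is counted over every pair of placements.  Oracle
    for small scopes only (<= 9 cells).
    """
    cells = list(range(m * n))
    hits = total = 0
    for a in combinations(cells, ka):
        sa = set(a)
        for b in combinations(cells, kb):
            total += 1
            if len(sa.intersection(b)) >= observed:
                hits += 1
    return hits / total


class TestFillPreserving:
    def test_conserves_link_count_and_shape(self, rng):
        lay = _layer(np.eye(5, 7, dtype=int))
        out = randomize_fill_preserving(lay, rng)
        assert out.shape == lay.shape
        assert out.n_links == lay.n_links
        assert out.weight is None

    def test_full_matrix_is_fixed_point(self, rng):
        lay = _layer(np.ones((2, 2), dtype=int))
        assert np.array_equal(randomize_fill_preserving(lay, rng).presence, lay.presence)

    def test_single_link_is_uniform_over_cells(self):
        lay = _layer([[1, 0], [0, 0]])
        rng = np.random.default_rng(7)
        counts = np.zeros(4)
        n = 4000
        for _ in range(n):
            counts += randomize_fill_preserving(lay, rng).presence.ravel()
        chi2 = (((counts - n / 4) ** 2) / (n / 4)).sum()
        assert chi2 < 16.27  # chi2_{3, 0.999}

    def test_fixed_seed_reproduces(self):
        lay = _layer(np.eye(4, dtype=int))
        a = randomize_fill_preserving(lay, 11).presence
        b = randomize_fill_preserving(lay, 11).presence
        assert np.array_equal(a, b)

    def test_refuses_seedless_call(self):
        with pytest.raises(ValueError, match="seed"):
            randomize_fill_preserving(_layer([[1, 0]]), None)


class TestDegreePreserving:
    def test_margins_conserved_on_random_matrix(self, rng):
        pres = (rng.random((10, 10)) < 0.3).astype(int)
        lay = _layer(pres)
        out = randomize_degree_preserving(lay, rng)
        assert np.array_equal(out.presence.sum(axis=1), pres.sum(axis=1))
        assert np.array_equal(out.presence.sum(axis=0), pres.sum(axis=0))

    def test_identity_2x2_stays_in_its_margin_class(self, rng):
        lay = _layer(np.eye(2, dtype=int))
        seen = set()
        for seed in range(20):
            out = randomize_degree_preserving(lay, np.random.default_rng(seed))
            seen.add(tuple(out.presence.ravel()))
        assert seen <= {(1, 0, 0, 1), (0, 1, 1, 0)}
        assert len(seen) == 2  # the chain does mix

    def test_rigid_matrix_unchanged(self, rng):
        lay = _layer([[1, 1], [1, 1], [0, 0]])
        out = randomize_degree_preserving(lay, rng)
        assert np.array_equal(out.presence, lay.presence)


class TestCe:
    def test_hand_computed_probabilities(self):
        prob = ce_probabilities(_layer([[1, 1], [1, 0]]))
        assert np.allclose(prob.probs, [[1.0, 0.75], [0.75, 0.5]])

    @pytest.mark.parametrize("fill_val", [0, 1])
    def test_constant_matrices_map_to_constant_probabilities(self, fill_val):
        prob = ce_probabilities(_layer(np.full((3, 4), fill_val)))
        assert np.all(prob.probs == fill_val)

    def test_mean_probability_equals_fill_exactly(self, rng):
        for _ in range(10):
            pres = (rng.random((6, 9)) < rng.random()).astype(int)
            lay = _layer(pres)
            assert np.mean(ce_probabilities(lay).probs) == pytest.approx(
                lay.fill, abs=1e-12
            )

    def test_sample_recovers_fill_within_monte_carlo_error(self):
        rng = np.random.default_rng(3)
        pres = (np.random.default_rng(0).random((8, 8)) < 0.4).astype(int)
        lay = _layer(pres)
        prob = ce_probabilities(lay)
        draws = np.array([sample_ce(prob, rng).mean() for _ in range(1000)])
        se = draws.std(ddof=1) / np.sqrt(len(draws))
        assert abs(draws.mean() - lay.fill) < 3 * max(se, 1e-6)

    def test_certain_cells_always_sampled(self, rng):
        prob = ce_probabilities(_layer(np.ones((3, 3), dtype=int)))
        assert np.all(sample_ce(prob, rng) == 1)


class TestDmNullTest:
    @staticmethod
    def _two_by_two_net():
        return build_network(
            [("pollination", "p1", "b1"), ("dispersal", "p1", "b1")]
        )

    def test_2x2_single_coincidence_has_exact_quarter_p(self):
        # the pair (p1,b1) is the only species pair; scope it as a 2x2 by
        # adding a second plant/bird in each layer
        net = build_network(
            [
                ("pollination", "p1", "b1"),
                ("dispersal", "p1", "b1"),
                ("pollination", "p2", "b2"),
                ("dispersal", "p2", "b2"),
            ]
        )
        # overlap scope is the 2x2 matrix with 2 links per layer: observed 2
        res = dm_null_test(net, scope="overlap", n=20_000, rng=5)
        exact = exact_dm_p(2, 2, 2, 2, res.observed)
        se = np.sqrt(exact * (1 - exact) / res.n_randomizations)
        assert abs(res.p_value - exact) < 3 * se + 1e-9

    def test_one_link_per_layer_quarter(self):
        # 2x2 scope with one link per layer: exact enumeration gives 1/4
        assert exact_dm_p(2, 2, 1, 1, 1) == pytest.approx(0.25)
        net = build_network(
            [
                ("pollination", "p1", "b1"),
                ("dispersal", "p1", "b2"),
                ("pollination", "p2", "b2"),  # keeps both species in overlap
                ("dispersal", "p2", "b1"),
            ]
        )
        sub = dm_null_test(net, scope="overlap", n=10_000, rng=6)
        assert sub.observed == 0
        assert sub.p_value == pytest.approx(1.0)

    @pytest.mark.parametrize("m,n,ka,kb", [(3, 3, 7, 5), (2, 4, 6, 5), (3, 3, 6, 6)])
    def test_monte_carlo_matches_enumeration_on_small_scopes(self, m, n, ka, kb):
        # dense fills keep every species linked, so the built network's
        # total scope is exactly the m x n matrix
        cells = [(i, j) for i in range(m) for j in range(n)]
        records = [("pollination", f"p{i}", f"b{j}") for i, j in cells[:ka]] + [
            ("dispersal", f"p{i}", f"b{j}") for i, j in cells[-kb:]
        ]
        net = build_network(records)
        res = dm_null_test(net, scope="total", n=30_000, rng=9)
        exact = exact_dm_p(m, n, ka, kb, res.observed)
        se = np.sqrt(exact * (1 - exact) / res.n_randomizations)
        assert abs(res.p_value - exact) < 3 * se + 1e-9
        # under uniform placement the coincidence count is hypergeometric
        assert exact == pytest.approx(
            float(hypergeom.sf(res.observed - 1, m * n, ka, kb))
        )

    def test_result_consistency_and_reproducibility(self, table1_net):
        a = dm_null_test(table1_net, scope="dm-submatrix", n=2000, rng=13)
        b = dm_null_test(table1_net, scope="dm-submatrix", n=2000, rng=13)
        assert np.array_equal(a.null_counts, b.null_counts)
        assert a.p_value == np.mean(a.null_counts >= a.observed)
        assert 0.0 <= a.p_value <= 1.0
        assert a.p_value_add_one > a.p_value * (2000 / 2001) - 1e-12

    def test_degree_preserving_and_ce_variants_run(self, table1_net):
        for kind in ("degree-preserving", "ce"):
            res = dm_null_test(table1_net, scope="dm-submatrix", n=30, null_kind=kind, rng=1)
            assert res.n_randomizations == 30
            assert 0 <= res.p_value <= 1

    def test_empty_scope_and_bad_n_raise(self):
        net = build_network(
            [("pollination", "p1", "b1"), ("dispersal", "p2", "b2")]
        )
        with pytest.raises(ValueError, match="empty"):
            dm_null_test(net, scope="overlap", n=10, rng=1)
        with pytest.raises(ValueError, match="n must be"):
            dm_null_test(net, scope="total", n=0, rng=1)
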