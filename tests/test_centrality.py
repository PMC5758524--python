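from itertools import combinations

import numpy as np
import pytest
from scipy.stats import mannwhitneyu

from mutualnet import (
    betweenness,
    build_network,
    classify_roles,
    compare_strength_by_role,
    correlate_linkage,
    dependencies,
    species_strength,
)
from mutualnet.centrality import rank_sum_permutation
from mutualnet.core import LayerMatrix


def _weighted_layer(weights, kind="pollination"):
    w = np.asarray(weights, dtype=float)
    m, n = w.shape
    return LayerMatrix(
        kind,
        [f"p{i}" for i in range(m)],
        [f"b{j}" for j in range(n)],
        (w > 0).astype(int),
        w,
    )


class TestBetweenness:
    def test_path_center_scores_one_and_ends_zero(self):
        net = build_network(
            [("pollination", "mid", "end1"), ("dispersal", "mid", "end2")]
        )
        table = betweenness(net).set_index("species")["betweenness"]
        assert table["mid"] == pytest.approx(1.0)
        assert table["end1"] == table["end2"] == 0.0

    def test_star_leaves_score_zero(self):
        net = build_network(
            [("pollination", "hub", f"leaf{i}") for i in range(5)]
        )
        table = betweenness(net).set_index("species")["betweenness"]
        assert table["hub"] == pytest.approx(1.0)
        assert (table.drop("hub") == 0).all()

    def test_complete_bipartite_single_layer_between_guilds(self):
        # in K2,2 every shortest path between same-guild species has two
        # equally short routes, so each opposite-guild node gets 1/2 of one
        # pair: score 2 * (1/2) / ((4-1)(4-2)/2) = 1/6... checked against
        # the networkx value rather than recomputed here
        net = build_network(
            [("pollination", p, b) for p in ("p1", "p2") for b in ("b1", "b2")]
        )
        table = betweenness(net)
        assert np.allclose(table["betweenness"], table["betweenness"].iloc[0])

    def test_too_small_network_rejected(self):
        net = build_network([("pollination", "p1", "b1")])
        with pytest.raises(ValueError, match="3 nodes"):
            betweenness(net)

    def test_role_group_means_on_reconstruction(self, table1_net):
        table = betweenness(table1_net)
        means = table.groupby("role")["betweenness"].mean()
        # the double mutualists sit in the link-dense core: their mean
        # betweenness dominates the single mutualists'
        singles = (
            means.get("single-pollination", 0.0) + means.get("single-dispersal", 0.0)
        ) / 2
        assert means["double-mutualist"] > means["pollinator-disperser"] > singles


class TestDependencies:
    def test_single_partner_full_dependency(self):
        lay = _weighted_layer([[7.0]])
        assert dependencies(lay, "plants").iloc[0, 0] == pytest.approx(1.0)

    def test_three_to_one_split(self):
        lay = _weighted_layer([[3.0, 1.0]])
        d = dependencies(lay, "plants")
        assert list(d.iloc[0]) == pytest.approx([0.75, 0.25])

    def test_zero_weight_row_stays_zero(self):
        lay = _weighted_layer([[0.0, 0.0], [1.0, 1.0]])
        d = dependencies(lay, "plants")
        assert (d.iloc[0] == 0).all()
        assert d.iloc[1].sum() == pytest.approx(1.0)

    def test_rows_sum_to_one_for_weighted_species(self, small_synthetic):
        for layer in (small_synthetic.pollination, small_synthetic.dispersal):
            d = dependencies(layer, "plants")
            pos = layer.weight.sum(axis=1) > 0
            assert np.allclose(d.to_numpy()[pos].sum(axis=1), 1.0)
            db = dependencies(layer, "birds")
            posb = layer.weight.sum(axis=0) > 0
            assert np.allclose(db.to_numpy()[posb].sum(axis=1), 1.0)

    def test_unweighted_layer_rejected(self, table1_net):
        with pytest.raises(ValueError, match="weighted"):
            dependencies(table1_net.pollination)


class TestStrength:
    def test_sole_partner_of_two_plants_has_strength_two(self):
        lay = _weighted_layer([[2.0], [5.0]])
        st = species_strength(lay).set_index("species")
        assert st.loc["b0", "strength"] == pytest.approx(2.0)

    def test_hand_computed_two_bird_example(self):
        # bird A: weights 3 on P1 and 2 on P2; bird B: 1 on P1
        lay = _weighted_layer([[3.0, 1.0], [2.0, 0.0]])
        st = species_strength(lay).set_index("species")
        assert st.loc["b0", "strength"] == pytest.approx(0.75 + 1.0)
        assert st.loc["b1", "strength"] == pytest.approx(0.25)

    def test_conservation_identity_exact(self, small_synthetic):
        for layer in (small_synthetic.pollination, small_synthetic.dispersal):
            st = species_strength(layer)
            birds = st[st.guild == "bird"]["strength"].sum()
            plants = st[st.guild == "plant"]["strength"].sum()
            n_weighted_plants = int((layer.weight.sum(axis=1) > 0).sum())
            n_weighted_birds = int((layer.weight.sum(axis=0) > 0).sum())
            assert birds == pytest.approx(n_weighted_plants, abs=1e-9)
            assert plants == pytest.approx(n_weighted_birds, abs=1e-9)


class TestRankSum:
    def test_identical_groups_are_unremarkable(self):
        res = rank_sum_permutation([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], rng=1, n_permutations=2000)
        assert res.p_value > 0.5

    def test_separated_groups_match_exact_enumeration(self):
        a, b = [1.0, 2.0, 3.0], [10.0, 11.0, 12.0]
        # exact two-sided permutation p over all C(6,3)=20 label splits
        pooled = a + b
        obs = mannwhitneyu(a, b, alternative="two-sided").statistic
        e_u = 9 / 2
        hits = 0
        for idx in combinations(range(6), 3):
            ga = [pooled[i] for i in idx]
            gb = [pooled[i] for i in range(6) if i not in idx]
            u = mannwhitneyu(ga, gb, alternative="two-sided").statistic
            hits += abs(u - e_u) >= abs(obs - e_u)
        exact = hits / 20
        assert exact == pytest.approx(0.1)
        res = rank_sum_permutation(a, b, rng=2, n_permutations=4000)
        se = np.sqrt(exact * (1 - exact) / 4000)
        assert abs(res.p_value - exact) < 3 * se + 1 / 4001

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            rank_sum_permutation([], [1.0], rng=1)

    def test_role_wrapper_compares_double_vs_single(self, small_synthetic):
        rc = classify_roles(small_synthetic)
        st = species_strength(small_synthetic.pollination)
        res = compare_strength_by_role(st, rc, rng=3, n_permutations=500)
        assert 0 < res.p_value <= 1
        assert res.n_a > 0 and res.n_b > 0


class TestLinkageCorrelation:
    def test_identical_layers_correlate_perfectly(self):
        records = [("pollination", f"p{i}", f"b{j}") for i in range(4) for j in range(i + 1)]
        records += [(("dispersal",) + r[1:]) for r in records]
        net = build_network(records)
        res = correlate_linkage(net, "bird")
        assert res.r == pytest.approx(1.0)

    def test_anticorrelated_degrees_give_minus_one(self):
        # bird j pollinates plants 0..j and disperses plants j..4: degrees
        # (k, K - k) across birds
        records = []
        for j in range(4):
            for i in range(j + 1):
                records.append(("pollination", f"p{i}", f"b{j}"))
            for i in range(j, 5):
                records.append(("dispersal", f"p{i}", f"b{j}"))
        net = build_network(records)
        res = correlate_linkage(net, "bird")
        assert res.r == pytest.approx(-1.0)

    def test_df_follows_shared_species_count(self, table1_net):
        res = correlate_linkage(table1_net, "bird")
        assert res.n == 17
        assert res.df == (1, 15)
        assert res.f_statistic > 0

    def test_zero_variance_predictor_rejected(self):
        records = [("pollination", f"p{i}", f"b{j}") for i in range(2) for j in range(3)]
        records += [("dispersal", f"p{j}", f"b{j}") for j in range(2)]
        records += [("dispersal", "p0", "b2")]
        net = build_network(records)
        with pytest.raises(ValueError, match="variance"):
            correlate_linkage(net, "bird")
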