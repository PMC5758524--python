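"""Betweenness by role, quantitative dependence/strength, and the
cross-layer linkage-level correlation.

Betweenness asks which species glue the pollination and dispersal parts of
the network together, so it is computed on the union graph with Freeman's
scaling 2/((n-1)(n-2)).  Dependence and strength use the quantitative
layers separately (pollen grains/mm^2 vs viable seeds per dropping have no
common currency): a plant's dependence on a bird is the bird's share of
the plant's total pollen (or seed) weight, and a bird's strength is the
sum of the dependencies of all plants on it — so bird strengths sum
exactly to the number of plants with positive weighted degree.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .core import LayerMatrix, MutualismNetwork, classify_roles, union_graph
from .nulls import as_rng

__all__ = [
    "betweenness",
    "dependencies",
    "species_strength",
    "rank_sum_permutation",
    "compare_strength_by_role",
    "correlate_linkage",
    "RankSumResult",
    "LinkageCorrelation",
]


def betweenness(net: MutualismNetwork, scope: str = "union") -> pd.DataFrame:
    """Scaled shortest-path betweenness per species, with roles attached.

    ``scope`` is ``"union"`` (both layers merged; the default, since the
    measure is about connecting the two functions) or a single layer kind.
    Returns a table (species, guild, role, betweenness); per-role means are
    a groupby away.
    """
    if scope == "union":
        g = union_graph(net)
    else:
        lay = net.layer(scope)
        g = nx.Graph()
        g.add_nodes_from(net.plants + net.birds)
        for i, p in enumerate(net.plants):
            for j, b in enumerate(net.birds):
                if lay.presence[i, j]:
                    g.add_edge(p, b)
    n = g.number_of_nodes()
    if n < 3:
        raise ValueError("betweenness scaling needs at least 3 nodes")
    bc = nx.betweenness_centrality(g, normalized=True)  # 2/((n-1)(n-2)) scaling
    rc = classify_roles(net)
    return pd.DataFrame(
        {
            "species": list(bc),
            "guild": [rc.guilds[v] for v in bc],
            "role": [rc.roles[v] for v in bc],
            "betweenness": list(bc.values()),
        }
    ).sort_values(["guild", "species"], ignore_index=True)


def role_group_means(bc_table: pd.DataFrame) -> pd.Series:
    """Mean betweenness per role, pooling both guilds."""
    return bc_table.groupby("role")["betweenness"].mean()


def dependencies(layer: LayerMatrix, of: str = "plants") -> pd.DataFrame:
    """Dependency matrix: each species' weight share on its partners.

    ``of="plants"`` gives d(plant i on bird j) = w_ij / sum_j' w_ij'
    (rows are plants and sum to 1 unless the plant has zero total weight,
    in which case its row is all zero).  ``of="birds"`` is the transposed
    normalization.
    """
    if layer.weight is None:
        raise ValueError("dependencies need a weighted layer")
    w = layer.weight
    if of == "plants":
        tot = w.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            d = np.where(tot > 0, w / tot, 0.0)
        return pd.DataFrame(d, index=layer.plants, columns=layer.birds)
    if of == "birds":
        tot = w.sum(axis=0, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            d = np.where(tot > 0, w / tot, 0.0)
        return pd.DataFrame(d.T, index=layer.birds, columns=layer.plants)
    raise ValueError("of must be 'plants' or 'birds'")


def species_strength(layer: LayerMatrix) -> pd.DataFrame:
    """Linkage level and strength per species for one quantitative layer.

    A bird's strength is the summed dependency of all plants on it, and
    symmetrically for plants.  Conservation identity: the bird strengths
    sum to the number of plants with positive weighted degree (and vice
    versa) — exact by construction.
    """
    d_plants = dependencies(layer, of="plants")  # plants x birds
    d_birds = dependencies(layer, of="birds")  # birds x plants
    deg_p = layer.presence.sum(axis=1)
    deg_b = layer.presence.sum(axis=0)
    rows = [
        {
            "species": p,
            "guild": "plant",
            "layer": layer.layer_kind,
            "degree": int(deg_p[i]),
            "strength": float(d_birds[p].sum()),
        }
        for i, p in enumerate(layer.plants)
    ] + [
        {
            "species": b,
            "guild": "bird",
            "layer": layer.layer_kind,
            "degree": int(deg_b[j]),
            "strength": float(d_plants[b].sum()),
        }
        for j, b in enumerate(layer.birds)
    ]
    return pd.DataFrame(rows)


@dataclass
class RankSumResult:
    statistic: float  # Mann-Whitney U of group A
    p_value: float  # two-sided permutation probability
    n_a: int
    n_b: int
    n_permutations: int


def rank_sum_permutation(
    values_a, values_b, rng=None, n_permutations: int = 10_000
) -> RankSumResult:
    """Two-sided rank-sum comparison with a permutation null.

    The statistic is the Mann-Whitney U of group A; labels are permuted
    (seeded) and the two-sided p is the fraction of permutations whose
    |U - E[U]| reaches the observed one, with the +1 correction so the
    observed arrangement counts as one permutation.
    """
    rng = as_rng(rng)
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    obs = stats.mannwhitneyu(a, b, alternative="two-sided").statistic
    pooled = np.concatenate([a, b])
    e_u = a.size * b.size / 2.0
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(pooled)
        u = stats.mannwhitneyu(perm[: a.size], perm[a.size :], alternative="two-sided").statistic
        if abs(u - e_u) >= abs(obs - e_u) - 1e-12:
            hits += 1
    return RankSumResult(
        float(obs), (hits + 1) / (n_permutations + 1), a.size, b.size, n_permutations
    )


def compare_strength_by_role(
    strengths: pd.DataFrame,
    roles,
    rng=None,
    group_a: str = "double-mutualist",
    group_b: tuple[str, ...] = ("single-pollination", "single-dispersal"),
    n_permutations: int = 10_000,
) -> RankSumResult:
    """Compare species strength between two role groups.

    ``strengths`` is a :func:`species_strength` table (one layer);
    ``roles`` a :class:`~mutualnet.core.RoleClassification`.  By default
    double mutualists are compared against the pooled single mutualists.
    """
    if isinstance(group_b, str):
        group_b = (group_b,)
    role_of = roles.roles
    vals_a = strengths.loc[
        strengths["species"].map(lambda s: role_of.get(s) == group_a), "strength"
    ]
    vals_b = strengths.loc[
        strengths["species"].map(lambda s: role_of.get(s) in group_b), "strength"
    ]
    return rank_sum_permutation(vals_a, vals_b, rng=rng, n_permutations=n_permutations)


@dataclass
class LinkageCorrelation:
    r: float
    f_statistic: float
    df: tuple[int, int]
    p_value: float
    n: int
    slope: float
    intercept: float


def correlate_linkage(net: MutualismNetwork, guild: str = "bird") -> LinkageCorrelation:
    """Regress dispersal degree on pollination degree across shared species.

    Scope is the species of one guild present in both layers (>= 1 link in
    each).  Degrees are binary linkage levels; the F statistic is the
    squared t of the slope with (1, n-2) degrees of freedom, so for the 17
    birds of the overlap area df = (1, 15).
    """
    if guild == "bird":
        kp = net.pollination.presence.sum(axis=0)
        ks = net.dispersal.presence.sum(axis=0)
    elif guild == "plant":
        kp = net.pollination.presence.sum(axis=1)
        ks = net.dispersal.presence.sum(axis=1)
    else:
        raise ValueError("guild must be 'bird' or 'plant'")
    shared = (kp > 0) & (ks > 0)
    x, y = kp[shared].astype(float), ks[shared].astype(float)
    if x.size < 3:
        raise ValueError("need at least 3 species present in both layers")
    if np.ptp(x) == 0:
        raise ValueError("predictor degrees have zero variance")
    fit = stats.linregress(x, y)
    df = (1, x.size - 2)
    t = fit.rvalue * np.sqrt(df[1] / (1.0 - fit.rvalue**2)) if abs(fit.rvalue) < 1 else np.inf
    return LinkageCorrelation(
        float(fit.rvalue),
        float(t**2),
        df,
        float(fit.pvalue),
        int(x.size),
        float(fit.slope),
        float(fit.intercept),
    )
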