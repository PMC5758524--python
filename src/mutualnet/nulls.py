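"""Randomization null models and the double-mutualism significance test.

The question the test answers: if pollination and seed-dispersal links were
laid down independently of each other, how surprising is the observed
number of coincident (plant, bird) pairs?  Both layers of a scoped
subnetwork are randomized, the coincidence count recorded, and a one-tailed
Monte-Carlo probability of reaching the observed count returned.

Three randomization engines are provided:

``fill-preserving``
    Links placed uniformly at random, holding only each layer's link total
    fixed (margins free).  Under this null the coincidence count is exactly
    hypergeometric, which the tests exploit as a closed-form oracle.
``degree-preserving``
    Checkerboard (2x2 swap) chain holding every row and column degree
    fixed.
``ce``
    Independent Bernoulli cells with occupancy probability equal to the
    mean of the cell's row fill and column fill; conserves overall fill in
    expectation and is the null used for nestedness.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import (
    LayerMatrix,
    MutualismNetwork,
    double_mutualism_submatrix,
    count_double_mutualisms,
    overlap_subnetwork,
)

__all__ = [
    "NullTestResult",
    "CeProbabilityMatrix",
    "as_rng",
    "randomize_fill_preserving",
    "randomize_degree_preserving",
    "ce_probabilities",
    "sample_ce",
    "dm_null_test",
]

NULL_KINDS = ("fill-preserving", "degree-preserving", "ce")
SCOPES = ("total", "overlap", "dm-submatrix")


def as_rng(seed) -> np.random.Generator:
    """Coerce an explicit seed or Generator; ``None`` is refused.

    Every stochastic entry point takes a ``seed`` argument and refuses a
    default so that results are reproducible by construction.
    """
    if seed is None:
        raise ValueError("an explicit seed (or numpy Generator) is required")
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass
class NullTestResult:
    observed: int
    n_randomizations: int
    null_counts: np.ndarray
    p_value: float
    null_kind: str
    scope: str
    seed: object

    @property
    def null_mean(self) -> float:
        return float(np.mean(self.null_counts))

    @property
    def null_sd(self) -> float:
        return float(np.std(self.null_counts, ddof=1))

    @property
    def p_value_add_one(self) -> float:
        """(k+1)/(n+1) estimator; never exactly 0 at finite n."""
        k = int(np.sum(self.null_counts >= self.observed))
        return (k + 1) / (self.n_randomizations + 1)


@dataclass
class CeProbabilityMatrix:
    """Per-cell occupancy probabilities for the Ce null."""

    probs: np.ndarray

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=float)
        if ((self.probs < 0) | (self.probs > 1)).any():
            raise ValueError("probabilities must lie in [0, 1]")


def randomize_fill_preserving(layer: LayerMatrix, rng) -> LayerMatrix:
    """Place the layer's links uniformly at random; weights are dropped."""
    rng = as_rng(rng)
    m, n = layer.shape
    k = layer.n_links
    if k > m * n:
        raise ValueError("more links than cells")
    flat = rng.choice(m * n, size=k, replace=False)
    pres = np.zeros(m * n, dtype=np.int8)
    pres[flat] = 1
    return LayerMatrix(layer.layer_kind, layer.plants, layer.birds, pres.reshape(m, n))


def randomize_degree_preserving(
    layer: LayerMatrix, rng, n_swaps: int | None = None
) -> LayerMatrix:
    """Checkerboard-swap chain conserving all row and column degrees.

    ``n_swaps`` is the number of attempted 2x2 swaps (default 10x the link
    count, a common burn-in for bipartite swap chains).
    """
    rng = as_rng(rng)
    pres = layer.presence.copy()
    links = np.argwhere(pres == 1)
    k = len(links)
    if k < 2:
        return LayerMatrix(layer.layer_kind, layer.plants, layer.birds, pres)
    if n_swaps is None:
        n_swaps = 10 * k
    picks = rng.integers(0, k, size=(n_swaps, 2))
    for a, b in picks:
        (r1, c1), (r2, c2) = links[a], links[b]
        if r1 == r2 or c1 == c2:
            continue
        if pres[r1, c2] or pres[r2, c1]:
            continue
        pres[r1, c1] = pres[r2, c2] = 0
        pres[r1, c2] = pres[r2, c1] = 1
        links[a] = (r1, c2)
        links[b] = (r2, c1)
    return LayerMatrix(layer.layer_kind, layer.plants, layer.birds, pres)


def ce_probabilities(layer: LayerMatrix) -> CeProbabilityMatrix:
    """Ce occupancy probabilities: mean of row fill and column fill.

    ``p[i, j] = (rowfill_i + colfill_j) / 2`` where ``rowfill_i`` is row
    i's links divided by the number of columns (and symmetrically).  The
    grand mean of the matrix equals the source fill exactly.
    """
    m, n = layer.shape
    if m == 0 or n == 0:
        raise ValueError("Ce probabilities undefined for zero-dimension input")
    rowfill = layer.presence.sum(axis=1) / n
    colfill = layer.presence.sum(axis=0) / m
    return CeProbabilityMatrix((rowfill[:, None] + colfill[None, :]) / 2.0)


def sample_ce(prob: CeProbabilityMatrix, rng, template: LayerMatrix | None = None):
    """Independent Bernoulli draw per cell.

    Returns a bare binary array, or a :class:`LayerMatrix` when a template
    supplies layer kind and species names.
    """
    rng = as_rng(rng)
    pres = (rng.random(prob.probs.shape) < prob.probs).astype(np.int8)
    if template is None:
        return pres
    return LayerMatrix(template.layer_kind, template.plants, template.birds, pres)


def _scope_network(net: MutualismNetwork, scope: str) -> MutualismNetwork:
    if scope == "total":
        return net
    if scope == "overlap":
        return overlap_subnetwork(net)
    if scope == "dm-submatrix":
        return double_mutualism_submatrix(net)
    raise ValueError(f"unknown scope {scope!r}; expected one of {SCOPES}")


def _null_counts_fill(cells: int, ka: int, kb: int, n: int, rng) -> np.ndarray:
    """Coincidence counts for n independent uniform placements of both layers."""
    out = np.empty(n, dtype=np.int64)
    chunk = max(1, min(n, int(2e7) // max(cells, 1)))
    done = 0
    rows = np.arange(chunk)
    while done < n:
        c = min(chunk, n - done)
        ia = np.argpartition(rng.random((c, cells)), ka - 1, axis=1)[:, :ka]
        ib = np.argpartition(rng.random((c, cells)), kb - 1, axis=1)[:, :kb]
        amask = np.zeros((c, cells), dtype=bool)
        np.put_along_axis(amask, ia, True, axis=1)
        out[done : done + c] = amask[rows[:c, None], ib].sum(axis=1)
        done += c
    return out


def dm_null_test(
    net: MutualismNetwork,
    scope: str = "overlap",
    n: int = 50_000,
    null_kind: str = "fill-preserving",
    rng=None,
) -> NullTestResult:
    """One-tailed randomization test for an excess of double mutualisms.

    Both layers of the scoped subnetwork are independently randomized ``n``
    times and the coincidence count recorded each time;
    ``p = #{null >= observed} / n`` (ties count toward the tail).
    """
    rng = as_rng(rng)
    if n < 1:
        raise ValueError("n must be >= 1")
    if null_kind not in NULL_KINDS:
        raise ValueError(f"unknown null kind {null_kind!r}")
    sub = _scope_network(net, scope)
    if sub.n_plants == 0 or sub.n_birds == 0:
        raise ValueError(f"scope {scope!r} selects an empty subnetwork")
    observed = count_double_mutualisms(sub)
    P, S = sub.pollination, sub.dispersal

    if null_kind == "fill-preserving":
        cells = sub.n_plants * sub.n_birds
        counts = _null_counts_fill(cells, P.n_links, S.n_links, n, rng)
    else:
        counts = np.empty(n, dtype=np.int64)
        if null_kind == "ce":
            prob_p, prob_s = ce_probabilities(P), ce_probabilities(S)
            for r in range(n):
                a = sample_ce(prob_p, rng)
                b = sample_ce(prob_s, rng)
                counts[r] = int(((a == 1) & (b == 1)).sum())
        else:  # degree-preserving
            for r in range(n):
                a = randomize_degree_preserving(P, rng)
                b = randomize_degree_preserving(S, rng)
                counts[r] = int(((a.presence == 1) & (b.presence == 1)).sum())

    p_value = float(np.sum(counts >= observed) / n)
    return NullTestResult(observed, n, counts, p_value, null_kind, scope, None)
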