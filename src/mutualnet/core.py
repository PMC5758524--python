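"""Two-layer plant-bird mutualism networks.

A mutualism network couples a pollination layer and a seed-dispersal layer
over a shared set of plant and bird species.  A *double mutualism* is a
(plant, bird) pair linked in both layers — the same bird both pollinates a
plant and disperses its seed.  This module builds the two-layer object from
interaction records, extracts the overlap area and the double-mutualism
submatrix, classifies every species into one of four mutualist roles, and
does the link accounting (with each double mutualism scored as a single
link) that connectance and link-share percentages are based on.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "LAYER_KINDS",
    "ROLES",
    "Species",
    "LayerMatrix",
    "MutualismNetwork",
    "RoleClassification",
    "LinkAccounting",
    "normalize_name",
    "build_network",
    "overlap_subnetwork",
    "double_mutualism_submatrix",
    "count_double_mutualisms",
    "connectance",
    "classify_roles",
    "link_accounting",
    "role_percentages",
    "round_half_up",
    "union_graph",
]

#: The two interaction layers of the network.
LAYER_KINDS = ("pollination", "dispersal")

#: The four mutualist roles.  "single-pollination" / "single-dispersal"
#: species interact in one layer only; a "pollinator-disperser" has links in
#: both layers but never to the same partner; a "double-mutualist" shares at
#: least one partner between the layers.
ROLES = (
    "single-pollination",
    "single-dispersal",
    "pollinator-disperser",
    "double-mutualist",
)

_WS = re.compile(r"\s+")


def normalize_name(name: str) -> str:
    """Normalize a species name: trim, collapse internal whitespace.

    Matching elsewhere is case-insensitive (via ``str.casefold``); the
    collapsed, original-case form is kept for display.
    """
    return _WS.sub(" ", name.strip())


def round_half_up(x: float) -> int:
    """Round half away from zero (report-style rounding, not banker's)."""
    return int(np.floor(abs(x) + 0.5) * np.sign(x)) if x else 0


@dataclass(frozen=True)
class Species:
    """A plant or bird with optional origin and abundance proxy.

    ``abundance`` is a non-negative proxy count (ringing totals for birds,
    flower counts for plants); it drives nothing in the qualitative
    analyses but is carried for abundance-aware consumers.
    """

    name: str
    guild: str  # "plant" | "bird"
    origin: str = "unknown"  # "native" | "introduced" | "unknown"
    abundance: float | None = None

    def __post_init__(self):
        if not self.name or not self.name.strip():
            raise ValueError("species name must be non-empty")
        if self.guild not in ("plant", "bird"):
            raise ValueError(f"unknown guild {self.guild!r}")
        if self.origin not in ("native", "introduced", "unknown"):
            raise ValueError(f"unknown origin {self.origin!r}")
        if self.abundance is not None and self.abundance < 0:
            raise ValueError("abundance must be >= 0")


@dataclass
class LayerMatrix:
    """A plants x birds incidence matrix for one interaction layer.

    ``presence`` is binary; ``weight`` (optional) holds positive interaction
    strengths — mean pollen grains/mm^2 on the bird's body for pollination,
    mean viable seeds per dropping for dispersal — and must be zero wherever
    ``presence`` is zero.
    """

    layer_kind: str
    plants: list[str]
    birds: list[str]
    presence: np.ndarray
    weight: np.ndarray | None = None

    def __post_init__(self):
        if self.layer_kind not in LAYER_KINDS:
            raise ValueError(f"unknown layer kind {self.layer_kind!r}")
        self.presence = np.asarray(self.presence)
        if self.presence.shape != (len(self.plants), len(self.birds)):
            raise ValueError("presence shape does not match species lists")
        if not np.isin(self.presence, (0, 1)).all():
            raise ValueError("presence must be binary")
        self.presence = self.presence.astype(np.int8)
        if self.weight is not None:
            self.weight = np.asarray(self.weight, dtype=float)
            if self.weight.shape != self.presence.shape:
                raise ValueError("weight shape does not match presence")
            if (self.weight < 0).any():
                raise ValueError("weights must be non-negative")
            if ((self.weight > 0) & (self.presence == 0)).any():
                raise ValueError("positive weight on an absent link")

    @property
    def shape(self) -> tuple[int, int]:
        return self.presence.shape

    @property
    def n_links(self) -> int:
        return int(self.presence.sum())

    @property
    def fill(self) -> float:
        """Realized fraction of cells (connectance of this layer, 0-1)."""
        return self.n_links / self.presence.size if self.presence.size else 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.presence, index=self.plants, columns=self.birds)


@dataclass
class MutualismNetwork:
    """The 2-layered network: pollination + dispersal over shared orderings."""

    pollination: LayerMatrix
    dispersal: LayerMatrix
    species: dict[str, Species] = field(default_factory=dict)

    def __post_init__(self):
        if self.pollination.plants != self.dispersal.plants:
            raise ValueError("layers must share the plant ordering")
        if self.pollination.birds != self.dispersal.birds:
            raise ValueError("layers must share the bird ordering")

    @property
    def plants(self) -> list[str]:
        return self.pollination.plants

    @property
    def birds(self) -> list[str]:
        return self.pollination.birds

    @property
    def n_plants(self) -> int:
        return len(self.plants)

    @property
    def n_birds(self) -> int:
        return len(self.birds)

    def layer(self, kind: str) -> LayerMatrix:
        if kind == "pollination":
            return self.pollination
        if kind == "dispersal":
            return self.dispersal
        raise ValueError(f"unknown layer kind {kind!r}")

    @property
    def union_presence(self) -> np.ndarray:
        """Binary matrix with a 1 wherever either layer has a link."""
        return (self.pollination.presence | self.dispersal.presence).astype(np.int8)

    @property
    def dm_mask(self) -> np.ndarray:
        """Boolean mask of coincident (double-mutualism) cells."""
        return (self.pollination.presence == 1) & (self.dispersal.presence == 1)

    def validate(self, reject_isolated: bool = True) -> None:
        """Check the shared-ordering and no-isolated-species invariants.

        Subnetworks extracted by scope rules may in principle strand a
        species with no remaining link, so derived networks validate with
        ``reject_isolated=False``.
        """
        u = self.union_presence
        if reject_isolated and u.size:
            if (u.sum(axis=1) == 0).any() or (u.sum(axis=0) == 0).any():
                raise ValueError("network contains isolated species")


@dataclass
class RoleClassification:
    """Per-species roles plus per-guild counts over the four roles."""

    roles: dict[str, str]  # species name -> role
    guilds: dict[str, str]  # species name -> guild

    def counts(self, guild: str) -> dict[str, int]:
        out = {r: 0 for r in ROLES}
        for sp, role in self.roles.items():
            if self.guilds[sp] == guild:
                out[role] += 1
        return out

    def guild_size(self, guild: str) -> int:
        return sum(1 for g in self.guilds.values() if g == guild)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"species": list(self.roles), "guild": [self.guilds[s] for s in self.roles],
             "role": list(self.roles.values())}
        ).sort_values(["guild", "species"], ignore_index=True)


@dataclass
class LinkAccounting:
    """Counts of the three link kinds; each double mutualism scored once."""

    n_p: int  # pollination-only pair links
    n_s: int  # dispersal-only pair links
    n_ps: int  # coincident pair links (double mutualisms)

    @property
    def n_total(self) -> int:
        return self.n_p + self.n_s + self.n_ps

    @property
    def percentages(self) -> dict[str, float]:
        t = self.n_total
        if t == 0:
            return {"p": 0.0, "s": 0.0, "ps": 0.0}
        return {"p": 100 * self.n_p / t, "s": 100 * self.n_s / t, "ps": 100 * self.n_ps / t}


def _merge_records(
    records: Iterable[Sequence],
) -> tuple[dict[tuple[str, str, str], list[float]], dict[str, str], dict[str, str]]:
    """Fold duplicate (layer, plant, bird) records: presence OR, weights pooled."""
    links: dict[tuple[str, str, str], list[float]] = {}
    plant_names: dict[str, str] = {}  # casefolded key -> display form
    bird_names: dict[str, str] = {}
    for rec in records:
        if len(rec) == 3:
            layer, plant, bird = rec
            weight = None
        elif len(rec) == 4:
            layer, plant, bird, weight = rec
        else:
            raise ValueError(f"record {rec!r} must be (layer, plant, bird[, weight])")
        layer = str(layer).strip().casefold()
        if layer not in LAYER_KINDS:
            raise ValueError(f"unknown layer kind {layer!r}")
        plant = normalize_name(str(plant))
        bird = normalize_name(str(bird))
        if not plant or not bird:
            raise ValueError(f"record {rec!r} has an empty species name")
        if weight is not None:
            weight = float(weight)
            if weight < 0:
                raise ValueError(f"negative weight in record {rec!r}")
        pk, bk = plant.casefold(), bird.casefold()
        plant_names.setdefault(pk, plant)
        bird_names.setdefault(bk, bird)
        key = (layer, pk, bk)
        links.setdefault(key, [])
        if weight is not None:
            links[key].append(weight)
    return links, plant_names, bird_names


def build_network(
    records: Iterable[Sequence],
    species_info: Mapping[str, Species] | None = None,
) -> MutualismNetwork:
    """Build a two-layer network from (layer, plant, bird[, weight]) records.

    Duplicate records for the same (layer, plant, bird) merge: presence by
    OR, weights by the mean of the weights supplied (records without a
    weight do not enter the mean).  Species orderings are lexicographic on
    the normalized names, so construction is deterministic.
    """
    links, plant_names, bird_names = _merge_records(records)
    if not links:
        raise ValueError("no interactions: record list is empty")
    plants = sorted(plant_names.values(), key=str.casefold)
    birds = sorted(bird_names.values(), key=str.casefold)
    p_idx = {name.casefold(): i for i, name in enumerate(plants)}
    b_idx = {name.casefold(): j for j, name in enumerate(birds)}

    layers = {}
    for kind in LAYER_KINDS:
        pres = np.zeros((len(plants), len(birds)), dtype=np.int8)
        wmat = np.zeros_like(pres, dtype=float)
        any_weight = False
        for (layer, pk, bk), weights in links.items():
            if layer != kind:
                continue
            i, j = p_idx[pk], b_idx[bk]
            pres[i, j] = 1
            if weights:
                wmat[i, j] = float(np.mean(weights))
                any_weight = True
        layers[kind] = LayerMatrix(
            kind, list(plants), list(birds), pres, wmat if any_weight else None
        )

    species = {}
    for name in plants:
        sp = (species_info or {}).get(name)
        species[name] = sp if sp is not None else Species(name, "plant")
    for name in birds:
        sp = (species_info or {}).get(name)
        species[name] = sp if sp is not None else Species(name, "bird")

    net = MutualismNetwork(layers["pollination"], layers["dispersal"], species)
    net.validate(reject_isolated=True)
    return net


def _subnetwork(net: MutualismNetwork, keep_p: np.ndarray, keep_b: np.ndarray) -> MutualismNetwork:
    plants = [p for p, k in zip(net.plants, keep_p) if k]
    birds = [b for b, k in zip(net.birds, keep_b) if k]
    layers = {}
    for kind in LAYER_KINDS:
        lay = net.layer(kind)
        pres = lay.presence[np.ix_(keep_p, keep_b)]
        w = lay.weight[np.ix_(keep_p, keep_b)] if lay.weight is not None else None
        layers[kind] = LayerMatrix(kind, plants, birds, pres, w)
    species = {s: net.species[s] for s in plants + birds if s in net.species}
    sub = MutualismNetwork(layers["pollination"], layers["dispersal"], species)
    sub.validate(reject_isolated=False)
    return sub


def overlap_subnetwork(net: MutualismNetwork) -> MutualismNetwork:
    """The overlap area: species with at least one link in *each* layer.

    Retained species need not share partners across layers — that stricter
    condition defines :func:`double_mutualism_submatrix`.  Idempotent.
    """
    keep_p = (net.pollination.presence.sum(axis=1) > 0) & (
        net.dispersal.presence.sum(axis=1) > 0
    )
    keep_b = (net.pollination.presence.sum(axis=0) > 0) & (
        net.dispersal.presence.sum(axis=0) > 0
    )
    return _subnetwork(net, keep_p, keep_b)


def double_mutualism_submatrix(net: MutualismNetwork) -> MutualismNetwork:
    """Species involved in >= 1 double mutualism, with all their links."""
    dm = net.dm_mask
    return _subnetwork(net, dm.any(axis=1), dm.any(axis=0))


def count_double_mutualisms(net: MutualismNetwork) -> int:
    """Number of (plant, bird) pairs linked in both layers."""
    return int(net.dm_mask.sum())


def connectance(net: MutualismNetwork, denominator_convention: str = "single") -> float:
    """Realized links as a percentage of possible plant x bird cells.

    ``"single"`` (the standard reading) scores each double mutualism once
    and divides by plants x birds.  ``"doubled"`` counts each layer's links
    separately against a 2 x plants x birds denominator — the natural
    alternative once a network has two layers.
    """
    if net.n_plants == 0 or net.n_birds == 0:
        raise ValueError("connectance undefined for a zero-dimension network")
    cells = net.n_plants * net.n_birds
    if denominator_convention == "single":
        acc = link_accounting(net)
        return 100.0 * acc.n_total / cells
    if denominator_convention == "doubled":
        return 100.0 * (net.pollination.n_links + net.dispersal.n_links) / (2 * cells)
    raise ValueError(f"unknown convention {denominator_convention!r}")


def classify_roles(net: MutualismNetwork) -> RoleClassification:
    """Sort every species into one of the four mutualist roles."""
    P, S = net.pollination.presence, net.dispersal.presence
    dm = net.dm_mask
    roles: dict[str, str] = {}
    guilds: dict[str, str] = {}

    def _role(has_p: bool, has_s: bool, has_dm: bool) -> str:
        if has_dm:
            return "double-mutualist"
        if has_p and has_s:
            return "pollinator-disperser"
        if has_p:
            return "single-pollination"
        if has_s:
            return "single-dispersal"
        # isolated species only arise in non-strict subnetworks
        return "single-pollination"

    for i, plant in enumerate(net.plants):
        roles[plant] = _role(P[i].any(), S[i].any(), dm[i].any())
        guilds[plant] = "plant"
    for j, bird in enumerate(net.birds):
        roles[bird] = _role(P[:, j].any(), S[:, j].any(), dm[:, j].any())
        guilds[bird] = "bird"
    return RoleClassification(roles, guilds)


def link_accounting(net: MutualismNetwork) -> LinkAccounting:
    """Count pollination-only, dispersal-only and coincident pair links."""
    P = net.pollination.presence.astype(bool)
    S = net.dispersal.presence.astype(bool)
    return LinkAccounting(
        n_p=int((P & ~S).sum()), n_s=int((~P & S).sum()), n_ps=int((P & S).sum())
    )


def union_graph(net: MutualismNetwork) -> nx.Graph:
    """Collapse both layers to one undirected unipartite simple graph.

    Nodes are all species (``guild`` attribute set); an edge joins a plant
    and a bird linked in either layer, with a ``layers`` attribute naming
    which ("pollination", "dispersal" or "both").  Species-level metrics
    that ask how the two ecosystem functions are glued together
    (betweenness, modularity) operate on this graph.
    """
    g = nx.Graph()
    for p in net.plants:
        g.add_node(p, guild="plant")
    for b in net.birds:
        g.add_node(b, guild="bird")
    P, S = net.pollination.presence, net.dispersal.presence
    for i, p in enumerate(net.plants):
        for j, b in enumerate(net.birds):
            if P[i, j] and S[i, j]:
                g.add_edge(p, b, layers="both")
            elif P[i, j]:
                g.add_edge(p, b, layers="pollination")
            elif S[i, j]:
                g.add_edge(p, b, layers="dispersal")
    return g


def role_percentages(rc: RoleClassification) -> pd.DataFrame:
    """Role shares (%) per guild and pooled; raw and report-rounded.

    Rounding is half-away-from-zero, which is how shares like 47.6% -> 48%
    appear in summary tables; the raw quotients are always retained.
    """
    rows = []
    for guild in ("plant", "bird", "all"):
        if guild == "all":
            size = len(rc.roles)
            counts = {r: 0 for r in ROLES}
            for g in ("plant", "bird"):
                for r, c in rc.counts(g).items():
                    counts[r] += c
        else:
            size = rc.guild_size(guild)
            counts = rc.counts(guild)
        for role in ROLES:
            raw = 100.0 * counts[role] / size if size else 0.0
            rows.append(
                {"guild": guild, "role": role, "count": counts[role],
                 "percent": raw, "percent_rounded": round_half_up(raw)}
            )
    return pd.DataFrame(rows)
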