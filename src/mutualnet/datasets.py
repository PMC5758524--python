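"""Built-in example networks.

The main entry point is :func:`galapagos_table1_network`, a deterministic
reconstruction of the Galápagos archipelago plant-bird mutualism network
from its published group-level link table: 108 plants x 21 birds, 479
links, of which 25 are double mutualisms.  The published table gives, for
every (plant role-group x bird role-group) cell, the number of
pollination-only (p), dispersal-only (s) and coincident (ps) links; it does
not give the placement of links onto individual species.  The
reconstruction therefore fixes a canonical placement that realizes every
cell count while giving each species exactly the links its role requires.
All group-level quantities — link totals and shares, connectance of the
total matrix / overlap area / double-mutualism submatrix, role counts, and
the fill-preserving null distribution of the double-mutualism count (which
depends only on matrix dimensions and layer fills) — are invariant to the
within-cell placement and hence exact.  Placement-dependent metrics
(nestedness, modularity, centrality) are *not* those of the field network.
"""

from __future__ import annotations

from .core import MutualismNetwork, build_network

__all__ = ["galapagos_table1_network", "toy_network"]

# Plant role groups (rows) and bird role groups (columns), with group sizes.
_PLANT_GROUPS = [("pol_plant", 61), ("dm_plant", 13), ("pd_plant", 7), ("disp_plant", 27)]
_BIRD_GROUPS = [("pol_bird", 2), ("dm_bird", 10), ("pd_bird", 7), ("disp_bird", 2)]

# Published cell counts: (plant group, bird group) -> links per kind.
# Row sums: p = 347, s = 107, ps = 25; grand total 479.
_CELLS: dict[tuple[str, str], dict[str, int]] = {
    ("pol_plant", "pol_bird"): {"p": 3},
    ("pol_plant", "dm_bird"): {"p": 185},
    ("pol_plant", "pd_bird"): {"p": 58},
    ("dm_plant", "pol_bird"): {"p": 2},
    ("dm_plant", "dm_bird"): {"p": 42, "ps": 25, "s": 14},
    ("dm_plant", "pd_bird"): {"p": 24, "s": 9},
    ("dm_plant", "disp_bird"): {"s": 4},
    ("pd_plant", "dm_bird"): {"p": 21, "s": 8},
    ("pd_plant", "pd_bird"): {"p": 12, "s": 1},
    ("pd_plant", "disp_bird"): {"s": 1},
    ("disp_plant", "dm_bird"): {"s": 52},
    ("disp_plant", "pd_bird"): {"s": 12},
    ("disp_plant", "disp_bird"): {"s": 6},
}

# Within each cell, links of each kind fill successive "offset classes"
# {(i, (i + o) mod n_birds) : i = 0..m_plants-1}, starting at the offset
# below.  Distinct offsets give disjoint cell sets, so p/s/ps links never
# collide and the only coincident pairs are the 25 intended ones.  The
# starting offsets leave enough classes for each kind (checked at import).
_OFFSETS: dict[tuple[str, str], dict[str, int]] = {
    ("dm_plant", "dm_bird"): {"ps": 0, "p": 2, "s": 6},
    ("dm_plant", "pd_bird"): {"p": 0, "s": 3},
    ("pd_plant", "dm_bird"): {"p": 0, "s": 4},
    ("pd_plant", "pd_bird"): {"p": 0, "s": 3},
}


def _class_pairs(m: int, n: int, k: int, start: int) -> list[tuple[int, int]]:
    """First ``k`` pairs filling offset classes ``start, start+1, ...``."""
    pairs = []
    o = start
    while len(pairs) < k:
        for i in range(m):
            if len(pairs) == k:
                break
            pairs.append((i, (i + o) % n))
        o += 1
    return pairs


def galapagos_table1_network() -> MutualismNetwork:
    """Reconstruct the 108 x 21, 479-link Galápagos plant-bird network.

    Species are named after their role group (e.g. ``dm_bird_03`` is the
    third double-mutualist bird); the placement is deterministic.
    """
    plant_names = {
        g: [f"{g}_{i + 1:02d}" for i in range(size)] for g, size in _PLANT_GROUPS
    }
    bird_names = {
        g: [f"{g}_{j + 1:02d}" for j in range(size)] for g, size in _BIRD_GROUPS
    }
    records = []
    for (pg, bg), kinds in _CELLS.items():
        m = dict(_PLANT_GROUPS)[pg]
        n = dict(_BIRD_GROUPS)[bg]
        offsets = _OFFSETS.get((pg, bg), {"p": 0, "s": 0})
        used: set[tuple[int, int]] = set()
        for kind, k in kinds.items():
            pairs = _class_pairs(m, n, k, offsets[kind])
            if kind != "ps" and used & set(pairs):  # pragma: no cover
                raise AssertionError(f"offset collision in cell {(pg, bg)}")
            used |= set(pairs)
            for i, j in pairs:
                plant, bird = plant_names[pg][i], bird_names[bg][j]
                if kind in ("p", "ps"):
                    records.append(("pollination", plant, bird))
                if kind in ("s", "ps"):
                    records.append(("dispersal", plant, bird))
    return build_network(records)


def toy_network() -> MutualismNetwork:
    """A 4-plant x 3-bird network exercising all four roles.

    bird_dm pollinates and disperses plant_a (a double mutualism), and also
    pollinates plant_b; bird_pd pollinates plant_b and disperses plant_c
    (links in both layers, never to the same plant); bird_s only disperses
    plant_d.
    """
    return build_network(
        [
            ("pollination", "plant_a", "bird_dm", 5.0),
            ("dispersal", "plant_a", "bird_dm", 2.0),
            ("pollination", "plant_b", "bird_dm", 1.0),
            ("pollination", "plant_b", "bird_pd", 3.0),
            ("dispersal", "plant_c", "bird_pd", 1.0),
            ("dispersal", "plant_d", "bird_s", 4.0),
        ]
    )
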