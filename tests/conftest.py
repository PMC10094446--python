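"""Shared fixtures: toy reconstructions, random trees, and brute-force oracles."""

from __future__ import annotations

import numpy as np
import pytest

from dendroquant.swc_io import DENDRITE, SOMA, Reconstruction, SwcRecord

MINIMAL_SWC = """\
# a minimal soma + two dendrites
1 1 0 0 0 3.0 -1
2 3 5 0 0 1.0 1
3 3 0 5 0 1.0 1
"""

ONE_CHANNEL_SWC = """\
# channels: ribosome
1 1 0 0 0 3.0 -1 0.5 100.0
2 3 5 0 0 1.0 1 0.5 100.0
3 3 0 5 0 1.0 1 0.5 100.0
"""


@pytest.fixture
def minimal_text() -> str:
    return MINIMAL_SWC


@pytest.fixture
def one_channel_text() -> str:
    return ONE_CHANNEL_SWC


def make_recon(edges, coords=None, radii=None, structures=None, signal=None):
    """Build a Reconstruction from a parent map.

    ``edges``: dict node_id -> parent_id (-1 for the root).  Coordinates
    default to distinct points on a line so every compartment has length 1.
    """
    ids = sorted(edges)
    coords = coords or {}
    radii = radii or {}
    structures = structures or {}
    signal = signal or {}
    records = []
    for i, nid in enumerate(ids):
        x, y, z = coords.get(nid, (float(i), 0.0, 0.0))
        records.append(
            SwcRecord(
                node_id=nid,
                structure_code=structures.get(nid, SOMA if edges[nid] == -1 else DENDRITE),
                x=x, y=y, z=z,
                radius=radii.get(nid, 1.0),
                parent_id=edges[nid],
                signal=tuple(signal.get(nid, ())),
            )
        )
    return Reconstruction(records=records, channel_names=[])


def random_tree_recon(rng: np.random.Generator, n_nodes: int) -> Reconstruction:
    """A random rooted tree with random geometry (independent of the
    package's synthetic growth model): node i attaches to a uniformly
    chosen earlier node."""
    edges = {1: -1}
    coords = {1: (0.0, 0.0, 0.0)}
    for i in range(2, n_nodes + 1):
        parent = int(rng.integers(1, i))
        edges[i] = parent
        px, py, pz = coords[parent]
        step = rng.uniform(0.5, 3.0)
        d = rng.normal(size=3)
        d /= np.linalg.norm(d)
        coords[i] = (px + step * d[0], py + step * d[1], pz + step * d[2])
    radii = {i: float(rng.uniform(0.2, 2.0)) for i in edges}
    return make_recon(edges, coords=coords, radii=radii)


def condensed_branch_count(tree) -> int:
    """Brute-force branch count: splice out pass-through nodes of the
    undirected graph and count the chains between critical nodes."""
    import networkx as nx

    G = nx.Graph()
    for c in tree.compartments:
        G.add_edge(c.parent, c.child)
    if G.number_of_edges() == 0:
        return 0
    keep = {n for n in G if n == tree.root_id or G.degree(n) != 2}
    seen: set[frozenset] = set()
    count = 0
    for n in keep:
        for nb in G.neighbors(n):
            e = frozenset((n, nb))
            if e in seen:
                continue
            chain = [e]
            prev, cur = n, nb
            while cur not in keep:
                nxt = next(x for x in G.neighbors(cur) if x != prev)
                chain.append(frozenset((cur, nxt)))
                prev, cur = cur, nxt
            seen.update(chain)
            count += 1
    return count
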