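"""Arbor-level morphometrics on rooted neuron trees.

The metrics implemented here are the ones that carry cohort-level phenotype
comparisons in dendrite morphogenesis studies of *Drosophila* larval
multidendritic (da) sensory neurons:

* **TDL** — total dendritic length, the sum of all dendritic compartment
  lengths (µm);
* **TDB** — total dendritic branches, the number of maximal unbranched
  segments delimited by the root, branch nodes and tips;
* **DBD** — dendritic branch density, TDB / TDL (branches per µm), which is
  the reciprocal of the mean branch length and separates arbor *complexity*
  from arbor *size*: a proportional hypotrophy that shrinks growth and
  branching together leaves DBD unchanged.

Branch counting convention: a *branch* is a maximal path whose interior
nodes have exactly one child, so TDB = n_tips + n_branch_nodes (the root is
excluded from the branch-node count and multifurcations count once).  With
this convention DBD is exactly the inverse of the average branch length.

Soma handling: compartments whose child node is soma-coded are excluded, so
the metrics describe the dendritic arbor only.  The convention is
configurable through ``include_structures``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .swc_io import DENDRITE, SOMA, Reconstruction

__all__ = [
    "NeuronTree",
    "MorphoMetrics",
    "build_tree",
    "path_distance",
    "enumerate_branches",
    "morpho_metrics",
    "percent_change",
]


@dataclass(frozen=True)
class Compartment:
    """A parent->child edge of the tree (the elementary unit of length)."""

    parent: int
    child: int
    length: float  # Euclidean distance between endpoints, µm
    diameter: float  # mean of endpoint diameters, µm
    dendritic: bool  # child node is not soma-coded


class NeuronTree:
    """A rooted tree built from a validated reconstruction.

    Nodes keep their SWC ids. ``compartments`` lists every parent->child
    edge with its Euclidean length and mean endpoint diameter; a compartment
    is *dendritic* when its child node is not soma-coded (the edge leaving
    the soma into the arbor therefore counts as dendritic).
    """

    def __init__(self, recon: Reconstruction):
        by_id = {r.node_id: r for r in recon.records}
        if len(by_id) != len(recon.records):
            raise ValueError("duplicate node ids; validate the reconstruction first")
        roots = [r.node_id for r in recon.records if r.parent_id == -1]
        if len(roots) != 1:
            raise ValueError(f"expected one root, found {len(roots)}")
        self.root_id: int = roots[0]
        self.nodes = by_id
        self.children: dict[int, list[int]] = {nid: [] for nid in by_id}
        self.compartments: list[Compartment] = []
        for r in recon.records:
            if r.parent_id == -1:
                continue
            p = by_id[r.parent_id]
            self.children[r.parent_id].append(r.node_id)
            length = float(
                np.sqrt((r.x - p.x) ** 2 + (r.y - p.y) ** 2 + (r.z - p.z) ** 2)
            )
            self.compartments.append(
                Compartment(
                    parent=r.parent_id,
                    child=r.node_id,
                    length=length,
                    diameter=r.radius + p.radius,  # mean of the two diameters
                    dendritic=r.structure_code != SOMA,
                )
            )
        self._check_tree()
        self._path_dist = self._accumulate_path_distances()

    def _check_tree(self) -> None:
        # iterative DFS from the root; a tree reaches every node exactly once
        seen = {self.root_id}
        stack = [self.root_id]
        while stack:
            cur = stack.pop()
            for ch in self.children[cur]:
                if ch in seen:
                    raise ValueError(f"cycle detected at node {ch}")
                seen.add(ch)
                stack.append(ch)
        if len(seen) != len(self.nodes):
            missing = set(self.nodes) - seen
            raise ValueError(
                f"disconnected component: {len(missing)} nodes unreachable "
                f"from root (e.g. {sorted(missing)[:3]})"
            )

    def _accumulate_path_distances(self) -> dict[int, float]:
        lengths = {c.child: c.length for c in self.compartments}
        dist = {self.root_id: 0.0}
        stack = [self.root_id]
        while stack:
            cur = stack.pop()
            for ch in self.children[cur]:
                dist[ch] = dist[cur] + lengths[ch]
                stack.append(ch)
        return dist

    # -- queries -----------------------------------------------------------

    def is_tip(self, node_id: int) -> bool:
        return not self.children[node_id]

    def is_branch_node(self, node_id: int) -> bool:
        """Non-root node with >= 2 children (a multifurcation counts once)."""
        return node_id != self.root_id and len(self.children[node_id]) >= 2

    @property
    def dendritic_compartments(self) -> list[Compartment]:
        return [c for c in self.compartments if c.dendritic]

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)


@dataclass(frozen=True)
class MorphoMetrics:
    """Per-neuron morphometric summary."""

    tdl: float  # total dendritic length, µm
    tdb: int  # total dendritic branches
    dbd: float | None  # branch density = tdb / tdl; None when tdl == 0
    n_tips: int
    n_branch_nodes: int
    max_path_distance: float  # µm
    degenerate: bool = False  # single-node tree: tdl = 0, dbd undefined


def build_tree(recon: Reconstruction) -> NeuronTree:
    """Build a :class:`NeuronTree`; raises on cycles or disconnection."""
    return NeuronTree(recon)


def path_distance(tree: NeuronTree, node_id: int) -> float:
    """Along-the-arbor distance from the root to ``node_id``, in µm."""
    try:
        return tree._path_dist[node_id]
    except KeyError:
        raise KeyError(f"unknown node id {node_id}") from None


def enumerate_branches(tree: NeuronTree) -> list[list[int]]:
    """Maximal unbranched segments, each as the node-id path between
    critical nodes (root, branch nodes, tips).

    The segments partition the compartment set: every parent->child edge
    belongs to exactly one segment.
    """
    branches: list[list[int]] = []
    # a new segment starts below the root and below every branch node
    starts: list[tuple[int, int]] = [(tree.root_id, ch) for ch in tree.children[tree.root_id]]
    while starts:
        origin, cur = starts.pop()
        path = [origin, cur]
        while len(tree.children[cur]) == 1:
            cur = tree.children[cur][0]
            path.append(cur)
        branches.append(path)
        for ch in tree.children[cur]:
            starts.append((cur, ch))
    return branches


def morpho_metrics(tree: NeuronTree) -> MorphoMetrics:
    """Compute TDL, TDB, DBD and supporting counts for one neuron.

    A single-node tree is reported as degenerate (tdl = 0, dbd = None)
    rather than raising or silently producing NaN.
    """
    dend = tree.dendritic_compartments
    tdl = float(sum(c.length for c in dend))
    branches = enumerate_branches(tree)
    # count only branches that contain at least one dendritic compartment
    dendritic_children = {c.child for c in dend}
    tdb = sum(1 for b in branches if any(n in dendritic_children for n in b[1:]))
    n_tips = sum(1 for nid in tree.nodes if tree.is_tip(nid) and nid != tree.root_id)
    n_branch = sum(1 for nid in tree.nodes if tree.is_branch_node(nid))
    max_pd = max(tree._path_dist.values())
    if tree.n_nodes == 1 or tdl == 0.0:
        return MorphoMetrics(
            tdl=0.0,
            tdb=0,
            dbd=None,
            n_tips=n_tips,
            n_branch_nodes=n_branch,
            max_path_distance=max_pd,
            degenerate=True,
        )
    return MorphoMetrics(
        tdl=tdl,
        tdb=tdb,
        dbd=tdb / tdl,
        n_tips=n_tips,
        n_branch_nodes=n_branch,
        max_path_distance=max_pd,
    )


def percent_change(case_values, control_values) -> float:
    """Percent change of the case group mean from the control group mean.

    ``100 * (mean(case) - mean(control)) / mean(control)``; this is the
    standard normalization for reporting cohort phenotypes relative to a
    genetic control.
    """
    case = np.asarray(list(case_values), dtype=float)
    control = np.asarray(list(control_values), dtype=float)
    if case.size == 0 or control.size == 0:
        raise ValueError("empty group")
    m0 = control.mean()
    if m0 == 0:
        raise ValueError("control mean is zero; percent change undefined")
    return float(100.0 * (case.mean() - m0) / m0)
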