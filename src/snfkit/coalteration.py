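"""Co-alteration counts, the thresholded graph and the threshold sweep.

The co-alteration matrix counts, for each pair of regions, the number of
studies reporting *both* regions abnormal — direction-blind: a decrease
co-occurring with an increase still counts as co-alteration.  Its diagonal
is the per-region abnormal-study count.  An undirected graph keeps an edge
wherever the pair count reaches a reproducibility threshold tau (default
2: replicated in at least two independent studies); nodes are restricted
to regions abnormal in at least one study, since never-abnormal regions
cannot bear edges and would deflate density.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import networkx as nx
import numpy as np

from .core import FingerprintMatrix, NetworkScheme, RegionRecord, UnknownIdentifierError

__all__ = [
    "DEFAULT_TAU",
    "CoalterationMatrix",
    "CoalterationGraph",
    "ThresholdSweep",
    "coalteration_matrix",
    "build_graph",
    "connected_modules",
    "greedy_modules",
    "node_strength",
    "threshold_sweep",
]

#: Minimal reproducibility threshold: co-occurrence in >= 2 independent studies.
DEFAULT_TAU = 2


@dataclass(frozen=True)
class CoalterationMatrix:
    """Symmetric pair-count matrix C over the full ROI axis."""

    regions: tuple[RegionRecord, ...]
    counts: np.ndarray  # |R| x |R|, non-negative integers

    def __post_init__(self) -> None:
        arr = np.array(self.counts, dtype=np.int64, copy=True)
        n = len(self.regions)
        if arr.shape != (n, n):
            raise ValueError(f"counts shape {arr.shape} does not match {n} regions")
        arr.setflags(write=False)
        object.__setattr__(self, "counts", arr)
        object.__setattr__(self, "regions", tuple(self.regions))

    @property
    def roi_ids(self) -> tuple[str, ...]:
        return tuple(r.roi_id for r in self.regions)

    @property
    def diagonal(self) -> np.ndarray:
        """Per-region abnormal-study counts C(r, r)."""
        return np.diagonal(self.counts)


@dataclass(frozen=True)
class CoalterationGraph:
    """Thresholded undirected co-alteration graph.

    ``graph`` nodes are roi_ids with attributes ``label`` and
    ``dominant_network``; edges carry integer ``weight`` = C(r1, r2).
    ``abnormal_only`` records that the node set excludes never-abnormal
    regions (the default and only mode).
    """

    graph: nx.Graph
    tau: int
    abnormal_only: bool = True

    @property
    def density(self) -> float:
        """2|E| / (|V| (|V|-1)) over the abnormal-report node set; 0 if |V| < 2."""
        n = self.graph.number_of_nodes()
        if n < 2:
            return 0.0
        return 2.0 * self.graph.number_of_edges() / (n * (n - 1))


@dataclass(frozen=True)
class ThresholdSweep:
    """Per-tau edge counts, densities, component partitions and seed persistence."""

    taus: tuple[int, ...]
    edge_counts: tuple[int, ...]
    densities: tuple[float, ...]
    components: tuple[tuple[frozenset[str], ...], ...]
    seed_set: tuple[str, ...]
    seed_persistent: tuple[bool, ...]


def coalteration_matrix(m: FingerprintMatrix) -> CoalterationMatrix:
    """C(r1, r2) = number of studies with both regions reported abnormal."""
    abnormal = (m.entries != 0).astype(np.int64)
    return CoalterationMatrix(m.regions, abnormal @ abnormal.T)


def build_graph(
    c: CoalterationMatrix,
    tau: int = DEFAULT_TAU,
    scheme: NetworkScheme | None = None,
) -> CoalterationGraph:
    """Threshold C at tau, keeping only regions abnormal in >= 1 study.

    Self-loops are excluded; each node is tagged with its dominant network
    under the scheme's priority order when a scheme is given.
    """
    if tau < 1:
        raise ValueError(f"tau must be a positive integer, got {tau}")
    g = nx.Graph()
    keep = np.flatnonzero(c.diagonal > 0)
    for i in keep.tolist():
        region = c.regions[i]
        g.add_node(
            region.roi_id,
            label=region.label,
            dominant_network=(
                scheme.dominant(region.roi_id) if scheme is not None
                else region.networks[0]
            ),
        )
    for a, i in enumerate(keep.tolist()):
        for j in keep[a + 1:].tolist():
            w = int(c.counts[i, j])
            if w >= tau:
                g.add_edge(c.regions[i].roi_id, c.regions[j].roi_id, weight=w)
    return CoalterationGraph(graph=g, tau=int(tau))


def connected_modules(g: CoalterationGraph) -> list[frozenset[str]]:
    """Connected components, ordered by (size desc, smallest member asc)."""
    comps = [frozenset(c) for c in nx.connected_components(g.graph)]
    return sorted(comps, key=lambda c: (-len(c), min(c)))


def greedy_modules(g: CoalterationGraph) -> list[frozenset[str]]:
    """Weighted greedy-modularity communities (non-default alternative to
    the connected-component definition of a module)."""
    if g.graph.number_of_nodes() == 0:
        return []
    comms = nx.community.greedy_modularity_communities(g.graph, weight="weight")
    return sorted((frozenset(c) for c in comms), key=lambda c: (-len(c), min(c)))


def node_strength(g: CoalterationGraph) -> dict[str, int]:
    """Sum of incident edge weights per node; isolated nodes have strength 0."""
    return {v: int(s) for v, s in g.graph.degree(weight="weight")}


def threshold_sweep(
    c: CoalterationMatrix,
    taus: Sequence[int] = (1, 2, 3),
    seed_set: Sequence[str] = (),
    scheme: NetworkScheme | None = None,
) -> ThresholdSweep:
    """Edge counts, densities, components and seed-module persistence per tau.

    ``seed_set`` names a designated module (e.g. the DMN-limbic-thalamic
    core); persistence at a threshold means all of its members lie in one
    connected component of that threshold's graph.  Taus must be strictly
    increasing, so edge sets are nested: E(tau') is a subset of E(tau) for
    tau' > tau.
    """
    taus = tuple(int(t) for t in taus)
    if not taus:
        raise ValueError("taus must be non-empty")
    if any(b <= a for a, b in zip(taus, taus[1:])):
        raise ValueError(f"taus must be strictly increasing, got {taus}")
    roi_ids = set(c.roi_ids)
    seed_set = tuple(seed_set)
    for roi in seed_set:
        if roi not in roi_ids:
            raise UnknownIdentifierError(f"seed roi_id {roi!r} not on the region axis")
    edge_counts, densities, components, persistent = [], [], [], []
    for tau in taus:
        g = build_graph(c, tau=tau, scheme=scheme)
        comps = connected_modules(g)
        edge_counts.append(g.graph.number_of_edges())
        densities.append(g.density)
        components.append(tuple(comps))
        present = [roi for roi in seed_set if g.graph.has_node(roi)]
        persistent.append(
            bool(seed_set)
            and len(present) == len(seed_set)
            and any(set(seed_set) <= comp for comp in comps)
        )
    return ThresholdSweep(
        taus=taus,
        edge_counts=tuple(edge_counts),
        densities=tuple(densities),
        components=tuple(components),
        seed_set=seed_set,
        seed_persistent=tuple(persistent),
    )
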