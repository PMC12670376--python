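"""Graph-based weighting strategies and closure-tree weight extraction.

A graph assigns a nonnegative weight to each elementary hypothesis (node)
and a transition matrix of edge fractions that says where a node's weight
flows when the node is removed (because its hypothesis was rejected, or
because the weights of an intersection hypothesis deeper in the closure
tree are being extracted).  Removing every node outside a subset ``J``
yields the weights ``w_{j,J}`` of the intersection hypothesis ``H_J``; the
result does not depend on the removal order.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping

import numpy as np

__all__ = ["GraphSpec", "WeightTable", "closure_weights", "remove_node"]

_ATOL = 1e-9


@dataclass(frozen=True)
class GraphSpec:
    """Nodal weights plus transition matrix over an ordered label set.

    ``weights[i]`` is the weight of hypothesis ``labels[i]``;
    ``transition[i, j]`` the fraction of node i's weight passed to node j
    on removal of node i.
    """

    labels: tuple[str, ...]
    weights: np.ndarray
    transition: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "labels", tuple(self.labels))
        w = np.asarray(self.weights, dtype=float)
        g = np.asarray(self.transition, dtype=float)
        k = len(self.labels)
        if len(set(self.labels)) != k:
            raise ValueError("node labels must be unique")
        if w.shape != (k,) or g.shape != (k, k):
            raise ValueError("weights / transition shapes do not match labels")
        if np.any(w < -_ATOL) or w.sum() > 1.0 + _ATOL:
            raise ValueError("node weights must be nonnegative and sum to <= 1")
        if np.any(g < -_ATOL) or np.any(np.abs(np.diag(g)) > _ATOL):
            raise ValueError("edge fractions must be nonnegative with zero diagonal")
        if np.any(g.sum(axis=1) > 1.0 + _ATOL):
            raise ValueError("each transition row must sum to <= 1")
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "transition", g)

    @classmethod
    def from_maps(cls, labels: Iterable[str], weights: Mapping[str, float],
                  transition: Mapping[str, Mapping[str, float]]) -> "GraphSpec":
        labels = tuple(labels)
        w = np.array([float(weights.get(l, 0.0)) for l in labels])
        g = np.array([[float(transition.get(i, {}).get(j, 0.0)) for j in labels]
                      for i in labels])
        return cls(labels, w, g)

    def weight_of(self, label: str) -> float:
        return float(self.weights[self.labels.index(label)])

    def is_exhaustive(self, atol: float = _ATOL) -> bool:
        """True when no weight can ever be lost: nodal weights and every
        transition row sum to exactly one."""
        return (abs(self.weights.sum() - 1.0) <= atol
                and np.all(np.abs(self.transition.sum(axis=1) - 1.0) <= atol))


def remove_node(graph: GraphSpec, label: str) -> GraphSpec:
    """Remove one node, propagating its weight and reconnecting loose edges.

    ``w_j <- w_j + w_i g_ij`` and
    ``g_jk <- (g_jk + g_ji g_ik) / (1 - g_ji g_ij)``; an edge whose
    denominator vanishes (the two nodes exchange all weight with each other)
    is set to zero.  The input graph is not modified.
    """
    if label not in graph.labels:
        raise KeyError(f"unknown node label {label!r}")
    i = graph.labels.index(label)
    keep = [j for j in range(len(graph.labels)) if j != i]
    w = graph.weights[keep] + graph.weights[i] * graph.transition[i, keep]
    g_old = graph.transition
    sub = g_old[np.ix_(keep, keep)]
    gji = g_old[keep, i][:, None]       # edges into the removed node
    gik = g_old[i, keep][None, :]       # edges out of the removed node
    # denominator 1 - g_ji * g_ij depends on the source row j only
    denom = 1.0 - g_old[keep, i] * g_old[i, keep]
    new_g = sub + gji * gik
    with np.errstate(divide="ignore", invalid="ignore"):
        new_g = np.where(denom[:, None] > _ATOL, new_g / np.where(
            denom[:, None] > _ATOL, denom[:, None], 1.0), 0.0)
    np.fill_diagonal(new_g, 0.0)
    new_g = np.clip(new_g, 0.0, 1.0)
    labels = tuple(graph.labels[j] for j in keep)
    return GraphSpec(labels, w, new_g)


@dataclass(frozen=True)
class WeightTable:
    """Weights ``w_{j,J}`` for every nonempty subset J of the label set.

    Subsets are keyed canonically by bitmask over the ordered labels so
    lookups are exact; ``entry`` accepts any iterable of labels.
    """

    labels: tuple[str, ...]
    entries: dict  # bitmask -> dict[label, float]

    def mask(self, subset: Iterable[str]) -> int:
        m = 0
        for l in subset:
            m |= 1 << self.labels.index(l)
        return m

    def subset_labels(self, mask: int) -> tuple[str, ...]:
        return tuple(l for i, l in enumerate(self.labels) if mask >> i & 1)

    def entry(self, subset: Iterable[str]) -> dict:
        m = self.mask(subset)
        if m not in self.entries:
            raise KeyError(f"no weights stored for subset {tuple(subset)}")
        return dict(self.entries[m])

    def __len__(self) -> int:
        return len(self.entries)

    def subsets(self):
        for m in sorted(self.entries):
            yield self.subset_labels(m), dict(self.entries[m])

    def restrict(self, labels: Iterable[str]) -> "WeightTable":
        """Sub-table containing only subsets of ``labels``."""
        keep = set(labels)
        entries = {m: dict(w) for m, w in self.entries.items()
                   if set(self.subset_labels(m)) <= keep}
        return WeightTable(self.labels, entries)


def closure_weights(graph: GraphSpec) -> WeightTable:
    """Extract ``w_{j,J}`` for all nonempty ``J`` by iterated node removal.

    Subset graphs are built by dynamic programming over the removal lattice:
    the graph for ``J`` is obtained from the graph for ``J + {i}`` by one
    node removal, so each of the ``2^k - 1`` subsets costs a single update.
    """
    k = len(graph.labels)
    full_mask = (1 << k) - 1
    graphs: dict[int, GraphSpec] = {full_mask: graph}
    entries: dict[int, dict] = {}
    for size in range(k, 0, -1):
        for combo in combinations(range(k), size):
            m = sum(1 << i for i in combo)
            if m not in graphs:
                # remove the highest-index absent label from a stored supergraph
                absent = next(i for i in range(k) if not m >> i & 1)
                parent = m | 1 << absent
                graphs[m] = remove_node(graphs[parent], graph.labels[absent])
            g = graphs[m]
            entries[m] = {l: float(w) for l, w in zip(g.labels, g.weights)}
    # drop graphs cache; keep only weights
    return WeightTable(graph.labels, entries)
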