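"""Null models: degree-preserving rewiring, and the lattice/random nulls
used by small-world propensity.

Rewiring follows the Maslov-Sneppen double-edge-swap scheme: two edges
(a,b) and (c,d) are replaced by (a,d) and (c,b) whenever that creates no
self-loop or multi-edge. Weights travel with their edges, so both the
binary degree sequence and the multiset of edge weights are preserved
exactly. The number of *attempted* swaps is ``iters_per_edge`` times the
edge count; on dense graphs most attempts are rejected, which is the
expected behaviour of the scheme, not an error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np
from numba import njit

from .connectome import (
    WeightedConnectome,
    clustering_coefficient,
    global_efficiency,
)
from .exceptions import ValidationError

__all__ = [
    "NullEnsemble",
    "rewire_degree_preserving",
    "random_null",
    "lattice_null",
    "build_ensemble",
]


@njit(cache=True)
def _swap_kernel(u, v, adj, e1, e2, flip):  # pragma: no cover - jitted
    nswap = 0
    for t in range(e1.shape[0]):
        i = e1[t]
        j = e2[t]
        if i == j:
            continue
        a = u[i]
        b = v[i]
        c = u[j]
        d = v[j]
        if flip[t]:
            c, d = d, c
        if a == c or a == d or b == c or b == d:
            continue
        if adj[a, d] or adj[c, b]:
            continue
        adj[a, b] = False
        adj[b, a] = False
        adj[c, d] = False
        adj[d, c] = False
        adj[a, d] = True
        adj[d, a] = True
        adj[c, b] = True
        adj[b, c] = True
        v[i] = d
        u[j] = c
        v[j] = b
        nswap += 1
    return nswap


def rewire_degree_preserving(
    c: WeightedConnectome, iters_per_edge: int = 10, seed: int = 0
) -> WeightedConnectome:
    """Randomise the topology by double-edge swaps, keeping degrees.

    Attempts ``iters_per_edge * n_edges`` swaps; each swap moves two edges
    (with their weights) to new endpoints without changing any node's
    degree. Deterministic given ``seed``. A graph that admits no legal
    swap (too small or saturated) is returned unchanged with a warning.
    """
    n = c.n_nodes
    iu, ju = np.triu_indices(n, k=1)
    present = c.weights[iu, ju] > 0
    u = iu[present].astype(np.int64)
    v = ju[present].astype(np.int64)
    w = c.weights[u, v].copy()
    n_edges = u.size
    if n_edges < 2:
        warnings.warn("graph has fewer than 2 edges; returning an identical copy")
        return c.with_weights(c.weights.copy())
    attempts = int(iters_per_edge) * n_edges
    rng = np.random.default_rng(seed)
    e1 = rng.integers(0, n_edges, size=attempts)
    e2 = rng.integers(0, n_edges, size=attempts)
    flip = rng.integers(0, 2, size=attempts).astype(np.bool_)
    adj = c.weights > 0
    nswap = _swap_kernel(u, v, adj.copy(), e1, e2, flip)
    if nswap == 0:
        warnings.warn("no legal edge swap found; returning an identical copy")
        return c.with_weights(c.weights.copy())
    out = np.zeros_like(c.weights)
    out[u, v] = w
    out[v, u] = w
    return c.with_weights(out)


def random_null(c: WeightedConnectome, seed: int = 0) -> WeightedConnectome:
    """Degree-preserving random null (delegates to the rewiring routine)."""
    return rewire_degree_preserving(c, iters_per_edge=10, seed=seed)


def lattice_null(c: WeightedConnectome, seed: int = 0) -> WeightedConnectome:
    """Weighted ring-lattice null with the source's edge count and weights.

    Edges are placed on the node pairs with the smallest ring distance
    (|i-j| modulo N), filling distance bands outward until the source's
    edge count is reached; partial bands are filled in a seeded random
    order. The source's edge weights are then assigned sorted, largest
    weights on the shortest ring distances — the construction used by the
    small-world-propensity lattice null. Degree distribution is as close
    to regular as the edge count allows; the weight multiset is preserved.
    """
    n = c.n_nodes
    weights_sorted = np.sort(c.edge_weights())[::-1]
    n_edges = weights_sorted.size
    iu, ju = np.triu_indices(n, k=1)
    diff = ju - iu
    ring = np.minimum(diff, n - diff)
    rng = np.random.default_rng(seed)
    # stable sort by ring distance with a seeded shuffle inside each band
    jitter = rng.random(ring.size)
    order = np.lexsort((jitter, ring))
    pick = order[:n_edges]
    out = np.zeros((n, n))
    out[iu[pick], ju[pick]] = weights_sorted
    out = out + out.T
    return c.with_weights(out)


@dataclass
class NullEnsemble:
    """A rewired ensemble with per-metric summaries.

    ``metric_ses`` holds sample standard deviation / sqrt(n_nulls), the
    standard error of the ensemble mean.
    """

    graphs: List[WeightedConnectome]
    source_id: Optional[str]
    seed: int
    metric_means: Dict[str, float] = field(default_factory=dict)
    metric_ses: Dict[str, float] = field(default_factory=dict)

    @property
    def n_nulls(self) -> int:
        return len(self.graphs)


_ENSEMBLE_METRICS = {
    "global_efficiency": global_efficiency,
    "clustering_coefficient": clustering_coefficient,
}


def build_ensemble(
    c: WeightedConnectome,
    n_nulls: int = 100,
    iters_per_edge: int = 10,
    seed: int = 0,
    source_id: Optional[str] = None,
    keep_graphs: bool = True,
) -> NullEnsemble:
    """Build ``n_nulls`` rewired copies (seeded ``seed + k``) and summarise
    global efficiency and clustering over the ensemble."""
    if n_nulls < 1:
        raise ValidationError("n_nulls must be >= 1")
    values: Dict[str, list] = {name: [] for name in _ENSEMBLE_METRICS}
    graphs: List[WeightedConnectome] = []
    for k in range(n_nulls):
        g = rewire_degree_preserving(c, iters_per_edge=iters_per_edge, seed=seed + k)
        if keep_graphs:
            graphs.append(g)
        for name, fn in _ENSEMBLE_METRICS.items():
            values[name].append(fn(g))
    means = {name: float(np.mean(vals)) for name, vals in values.items()}
    if n_nulls == 1:
        warnings.warn("standard error undefined for a single null; reporting 0")
        ses = {name: 0.0 for name in values}
    else:
        ses = {
            name: float(np.std(vals, ddof=1) / np.sqrt(n_nulls))
            for name, vals in values.items()
        }
    return NullEnsemble(
        graphs=graphs,
        source_id=source_id,
        seed=seed,
        metric_means=means,
        metric_ses=ses,
    )
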