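"""Weighted structural connectomes and their basic global graph measures.

A structural connectome is modelled as a weighted, undirected graph whose
nodes are parcellated grey-matter regions and whose edge weights are
tractography-derived streamline strengths (dimensionless, non-negative).
Shortest-path based measures convert strengths into lengths via the
reciprocal, ``length = 1 / weight``, so that strongly connected region
pairs are topologically close.
"""

from __future__ import annotations

import io

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, shortest_path

from .exceptions import FormatError, UndefinedMetricError, ValidationError

__all__ = [
    "WeightedConnectome",
    "load_connectome",
    "write_connectome",
    "density",
    "median_edge_weight",
    "global_efficiency",
    "characteristic_path_length",
    "clustering_coefficient",
]

_SYM_ATOL = 1e-9


@dataclass(frozen=True)
class WeightedConnectome:
    """A symmetric, non-negative, zero-diagonal weight matrix with labels.

    Parameters
    ----------
    labels
        Unique region identifiers, one per node (length N, N >= 2).
    weights
        N x N matrix of connection strengths. Must be symmetric within
        1e-9 absolute tolerance (it is stored exactly symmetrised) with an
        exactly zero diagonal and no negative or non-finite entries.
    coords
        Optional N x 3 node positions in millimetres.
    """

    labels: tuple
    weights: np.ndarray
    coords: Optional[np.ndarray] = field(default=None)

    def __post_init__(self):
        labels = tuple(self.labels)
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise FormatError(f"weight matrix must be square, got shape {w.shape}")
        n = w.shape[0]
        if n < 2:
            raise ValidationError("a connectome needs at least 2 nodes")
        if len(labels) != n:
            raise ValidationError(f"{len(labels)} labels for {n} nodes")
        if len(set(labels)) != n:
            raise ValidationError("region labels must be unique")
        if not np.isfinite(w).all():
            raise ValidationError("weights contain NaN or infinite entries")
        if (w < 0).any():
            raise ValidationError("negative connection weights are not allowed")
        if not np.allclose(w, w.T, rtol=0.0, atol=_SYM_ATOL):
            i, j = np.unravel_index(np.argmax(np.abs(w - w.T)), w.shape)
            raise ValidationError(
                f"weights asymmetric beyond tolerance at ({labels[i]}, {labels[j]})"
            )
        if np.any(np.diag(w) != 0.0):
            raise ValidationError("diagonal must be exactly zero (no self-loops)")
        w = (w + w.T) / 2.0
        np.fill_diagonal(w, 0.0)
        w.flags.writeable = False
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "weights", w)
        if self.coords is not None:
            c = np.asarray(self.coords, dtype=float)
            if c.shape != (n, 3):
                raise ValidationError(f"coords must be ({n}, 3), got {c.shape}")
            c.flags.writeable = False
            object.__setattr__(self, "coords", c)

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    @property
    def n_edges(self) -> int:
        iu = np.triu_indices(self.n_nodes, k=1)
        return int(np.count_nonzero(self.weights[iu]))

    def edge_weights(self) -> np.ndarray:
        """Weights of present edges, each unordered pair counted once."""
        iu = np.triu_indices(self.n_nodes, k=1)
        w = self.weights[iu]
        return w[w > 0]

    def degrees(self) -> np.ndarray:
        """Binary degree of each node."""
        return (self.weights > 0).sum(axis=1)

    def with_weights(self, weights: np.ndarray) -> "WeightedConnectome":
        """New connectome with the same labels/coords and a new matrix."""
        return WeightedConnectome(self.labels, weights, self.coords)


# ---------------------------------------------------------------------------
# I/O: delimited-text matrices, optional first row+column of labels
# ---------------------------------------------------------------------------

def _sniff_delimiter(line: str) -> str:
    return "\t" if line.count("\t") >= line.count(",") else ","


def load_connectome(path, delimiter: Optional[str] = None) -> WeightedConnectome:
    """Read a connectome matrix from delimited text.

    The file holds a square numeric matrix, optionally preceded by a header
    row of labels (and then a matching first column of labels). Asymmetry
    within 1e-9 is symmetrised by averaging; anything worse is rejected.
    """
    path = Path(path)
    text = path.read_text()
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    if not lines:
        raise FormatError(f"{path}: empty matrix file")
    if delimiter is None:
        delimiter = _sniff_delimiter(lines[0])
    first = lines[0].split(delimiter)

    def _is_number(tok: str) -> bool:
        try:
            float(tok)
            return True
        except ValueError:
            return False

    has_header = not all(_is_number(t) for t in first if t.strip() != "")
    body = "\n".join(lines)
    try:
        if has_header:
            df = pd.read_csv(io.StringIO(body), sep=delimiter, index_col=0)
            labels = [str(x) for x in df.index]
            if [str(c) for c in df.columns] != labels:
                raise FormatError(f"{path}: row and column labels disagree")
            values = df.to_numpy(dtype=float)
        else:
            df = pd.read_csv(io.StringIO(body), sep=delimiter, header=None)
            values = df.to_numpy(dtype=float)
            labels = [f"n{i:03d}" for i in range(values.shape[0])]
    except ValueError as exc:
        raise FormatError(f"{path}: could not parse matrix ({exc})") from exc
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise FormatError(f"{path}: matrix is not square, shape {values.shape}")
    if np.isnan(values).any():
        raise ValidationError(f"{path}: matrix contains missing values")
    return WeightedConnectome(labels, values)


def write_connectome(c: WeightedConnectome, path, delimiter: str = ",") -> None:
    """Write the matrix with a label header; round-trips exactly."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(delimiter.join([""] + list(map(str, c.labels))) + "\n")
        for lab, row in zip(c.labels, c.weights):
            fh.write(str(lab) + delimiter)
            fh.write(delimiter.join(f"{v:.17g}" for v in row) + "\n")


# ---------------------------------------------------------------------------
# Global graph measures
# ---------------------------------------------------------------------------

def density(c: WeightedConnectome) -> float:
    """Fraction of present over possible connections."""
    n = c.n_nodes
    return c.n_edges / (n * (n - 1) / 2)


def median_edge_weight(c: WeightedConnectome) -> float:
    """Median over the weights of present edges (zeros excluded)."""
    w = c.edge_weights()
    if w.size == 0:
        raise UndefinedMetricError("median edge weight undefined for an edgeless graph")
    return float(np.median(w))


def _length_graph(weights: np.ndarray) -> csr_matrix:
    """Sparse matrix of reciprocal-weight edge lengths."""
    lengths = np.zeros_like(weights)
    mask = weights > 0
    lengths[mask] = 1.0 / weights[mask]
    return csr_matrix(lengths)


def shortest_path_lengths(c: WeightedConnectome) -> np.ndarray:
    """All-pairs shortest path lengths with length(i,j) = 1/w_ij.

    Disconnected pairs are +inf; the diagonal is 0.
    """
    return shortest_path(_length_graph(c.weights), method="D", directed=False)


def global_efficiency(c: WeightedConnectome) -> float:
    """Average inverse shortest path length over ordered node pairs.

    Disconnected pairs contribute 0, so the measure is defined on any
    graph. Covariant under global weight rescaling (efficiency scales with
    the weights); see :func:`csvdnet.metrics.compute_metrics` for the
    max-scaled, scale-free report.
    """
    d = shortest_path_lengths(c)
    n = c.n_nodes
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    return float(inv.sum() / (n * (n - 1)))


def characteristic_path_length(c: WeightedConnectome) -> float:
    """Mean shortest path length over connected ordered pairs."""
    d = shortest_path_lengths(c)
    n = c.n_nodes
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(d) & off
    if not finite.any():
        raise UndefinedMetricError("no connected node pairs")
    return float(d[finite].mean())


def largest_component(c: WeightedConnectome) -> WeightedConnectome:
    """Subgraph induced by the largest connected component."""
    n_comp, member = connected_components(csr_matrix(c.weights), directed=False)
    if n_comp == 1:
        return c
    sizes = np.bincount(member)
    keep = np.flatnonzero(member == np.argmax(sizes))
    if keep.size < 2:
        raise UndefinedMetricError("largest component has fewer than 2 nodes")
    sub = c.weights[np.ix_(keep, keep)]
    labels = [c.labels[i] for i in keep]
    coords = c.coords[keep] if c.coords is not None else None
    return WeightedConnectome(labels, sub, coords)


def clustering_coefficient(c: WeightedConnectome) -> float:
    """Mean Onnela weighted clustering coefficient.

    Weights are scaled by the matrix maximum, then
    ``C_i = (2 / (k_i (k_i - 1))) * sum_{(j,h)} (w_ij w_ih w_jh)^(1/3)``
    over unordered neighbour pairs; nodes of degree < 2 contribute 0.
    Invariant under global weight rescaling.
    """
    w = c.weights
    wmax = w.max()
    if wmax == 0:
        return 0.0
    cr = np.cbrt(w / wmax)
    # diag of cr^3 counts ordered (j, h) pairs = 2 x the unordered sum
    tri = np.diagonal(cr @ cr @ cr)
    k = c.degrees().astype(float)
    denom = k * (k - 1)
    ci = np.where(denom > 0, tri / np.where(denom > 0, denom, 1.0), 0.0)
    return float(ci.mean())
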