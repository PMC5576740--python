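"""Reading, writing and in-memory representation of graphs and node attributes.

Networks are undirected simple graphs given as plain-text edge lists (two
whitespace-separated node identifiers per line, ``#`` comments allowed).
Node attributes come either as a "bag" file — one line per node listing the
names of the attributes it carries — or as a dense numeric table with a
header row of attribute names.

The attribute matrix ``B`` is stored attributes-in-rows / nodes-in-columns
(shape ``m x n``), so that the attribute coefficient matrix shares the
``k x n`` node-embedding orientation of the topology coefficient matrix.
Each node's attribute vector (a column of ``B``) is L1-normalized, which
puts every entry in [0, 1] for non-negative input.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Graph",
    "AttributeMatrix",
    "GraphFormatError",
    "read_edge_list",
    "write_edge_list",
    "read_attributes",
    "write_attributes",
    "normalize_attributes",
]


class GraphFormatError(ValueError):
    """Raised for malformed or inconsistent edge-list / attribute input."""


@dataclass
class Graph:
    """An undirected simple graph with indexed nodes.

    Attributes
    ----------
    node_ids : list of str
        Original node identifiers in first-appearance order.  Internal
        indexing is 0-based positional.
    edges : set of (int, int)
        Unordered edges stored as index pairs with ``i < j``.  No
        self-loops, no duplicates.
    """

    node_ids: list[str]
    edges: set[tuple[int, int]] = field(default_factory=set)

    def __post_init__(self) -> None:
        n = len(self.node_ids)
        canon = set()
        for i, j in self.edges:
            if i == j:
                raise GraphFormatError(f"self-loop on node index {i}")
            if not (0 <= i < n and 0 <= j < n):
                raise GraphFormatError(f"edge ({i}, {j}) out of range for n={n}")
            canon.add((min(i, j), max(i, j)))
        self.edges = canon

    @property
    def n(self) -> int:
        return len(self.node_ids)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def index(self) -> dict[str, int]:
        return {name: i for i, name in enumerate(self.node_ids)}

    def adjacency(self, dtype=np.float64) -> np.ndarray:
        """Symmetric 0/1 adjacency matrix ``A`` with zero diagonal."""
        A = np.zeros((self.n, self.n), dtype=dtype)
        if self.edges:
            idx = np.array(sorted(self.edges))
            A[idx[:, 0], idx[:, 1]] = 1
            A[idx[:, 1], idx[:, 0]] = 1
        return A

    def subgraph_with_edges(self, edges: Iterable[tuple[int, int]]) -> "Graph":
        """Same node set, restricted edge set (used for train folds)."""
        return Graph(self.node_ids, {(min(i, j), max(i, j)) for i, j in edges})


@dataclass
class AttributeMatrix:
    """Non-negative node attributes, attributes in rows, nodes in columns."""

    attribute_names: list[str]
    matrix: np.ndarray  # m x n

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.ndim != 2:
            raise GraphFormatError("attribute matrix must be 2-D")
        if self.matrix.shape[0] != len(self.attribute_names):
            raise GraphFormatError(
                f"{len(self.attribute_names)} attribute names for "
                f"{self.matrix.shape[0]} matrix rows"
            )
        if np.any(self.matrix < 0):
            raise GraphFormatError("attribute values must be non-negative")

    @property
    def m(self) -> int:
        return self.matrix.shape[0]

    @property
    def n(self) -> int:
        return self.matrix.shape[1]


def read_edge_list(path, comment_prefix: str = "#") -> Graph:
    """Parse a two-column edge list into a :class:`Graph`.

    Nodes are indexed in first-appearance order.  Duplicate edges (in either
    orientation) are collapsed; self-loops are dropped with a warning.
    Lines may carry more than two tokens; only the first two are used.
    """
    node_ids: list[str] = []
    index: dict[str, int] = {}
    edges: set[tuple[int, int]] = set()
    n_loops = 0
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(comment_prefix):
                continue
            tokens = line.split()
            if len(tokens) < 2:
                raise GraphFormatError(
                    f"{path}: line {lineno}: expected two node identifiers, "
                    f"got {line!r}"
                )
            pair = []
            for tok in tokens[:2]:
                if tok not in index:
                    index[tok] = len(node_ids)
                    node_ids.append(tok)
                pair.append(index[tok])
            a, b = pair
            if a == b:
                n_loops += 1
                continue
            edges.add((min(a, b), max(a, b)))
    if n_loops:
        logger.warning("%s: dropped %d self-loop(s)", path, n_loops)
    return Graph(node_ids, edges)


def write_edge_list(graph: Graph, path, header: str | None = None) -> None:
    """Write one ``u v`` line per edge, original identifiers, sorted by index."""
    with open(path, "wt", encoding="utf-8") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        for i, j in sorted(graph.edges):
            fh.write(f"{graph.node_ids[i]} {graph.node_ids[j]}\n")


def normalize_attributes(raw: np.ndarray | AttributeMatrix,
                         attribute_names: Sequence[str] | None = None) -> AttributeMatrix:
    """L1-normalize each node's attribute vector (columns of the m x n matrix).

    Columns summing to zero are left all-zero.  Idempotent.
    """
    if isinstance(raw, AttributeMatrix):
        names = raw.attribute_names
        mat = raw.matrix
    else:
        mat = np.asarray(raw, dtype=np.float64)
        names = list(attribute_names) if attribute_names is not None else [
            f"attr_{i}" for i in range(mat.shape[0])
        ]
    if np.any(mat < 0):
        raise GraphFormatError("attribute values must be non-negative")
    sums = mat.sum(axis=0, keepdims=True)
    out = np.divide(mat, sums, out=np.zeros_like(mat), where=sums > 0)
    return AttributeMatrix(list(names), out)


def read_attributes(path, graph: Graph, mode: str = "bag",
                    comment_prefix: str = "#") -> AttributeMatrix:
    """Read node attributes and return them L1-normalized per node.

    ``bag`` mode: each line is a node identifier followed by the names of the
    attributes present on that node (binary incidence).  ``dense`` mode: a
    header line of attribute names, then one line per node with the node
    identifier followed by that many non-negative numeric values.

    Every node identifier in the file must belong to ``graph``; nodes absent
    from the file get an all-zero attribute vector.
    """
    if mode not in ("bag", "dense"):
        raise GraphFormatError(f"unknown attribute file mode {mode!r}")
    index = graph.index
    with open(path, "rt", encoding="utf-8") as fh:
        lines = [
            (no, ln.strip()) for no, ln in enumerate(fh, start=1)
            if ln.strip() and not ln.strip().startswith(comment_prefix)
        ]
    if mode == "bag":
        attr_index: dict[str, int] = {}
        per_node: dict[int, list[int]] = {}
        for lineno, line in lines:
            tokens = line.split()
            node, attrs = tokens[0], tokens[1:]
            if node not in index:
                raise GraphFormatError(
                    f"{path}: line {lineno}: unknown node identifier {node!r}"
                )
            slots = per_node.setdefault(index[node], [])
            for name in attrs:
                if name not in attr_index:
                    attr_index[name] = len(attr_index)
                slots.append(attr_index[name])
        raw = np.zeros((len(attr_index), graph.n))
        for col, rows in per_node.items():
            raw[rows, col] = 1.0
        names = list(attr_index)
    else:
        if not lines:
            raise GraphFormatError(f"{path}: empty dense attribute file")
        names = lines[0][1].split()
        raw = np.zeros((len(names), graph.n))
        for lineno, line in lines[1:]:
            tokens = line.split()
            node, values = tokens[0], tokens[1:]
            if node not in index:
                raise GraphFormatError(
                    f"{path}: line {lineno}: unknown node identifier {node!r}"
                )
            if len(values) != len(names):
                raise GraphFormatError(
                    f"{path}: line {lineno}: expected {len(names)} values, "
                    f"got {len(values)}"
                )
            vec = np.array([float(v) for v in values])
            if np.any(vec < 0):
                raise GraphFormatError(
                    f"{path}: line {lineno}: negative attribute value"
                )
            raw[:, index[node]] = vec
    if raw.size == 0:
        warnings.warn(f"{path}: no attributes found; attribute matrix is empty")
    return normalize_attributes(raw, names)


def write_attributes(attrs: AttributeMatrix, graph: Graph, path,
                     mode: str = "bag") -> None:
    """Write attributes in the format :func:`read_attributes` parses.

    In ``bag`` mode any strictly positive entry counts as "present".
    """
    if mode not in ("bag", "dense"):
        raise GraphFormatError(f"unknown attribute file mode {mode!r}")
    with open(path, "wt", encoding="utf-8") as fh:
        if mode == "bag":
            for col, node in enumerate(graph.node_ids):
                present = [
                    attrs.attribute_names[row]
                    for row in np.nonzero(attrs.matrix[:, col] > 0)[0]
                ]
                fh.write(" ".join([node, *present]) + "\n")
        else:
            fh.write(" ".join(attrs.attribute_names) + "\n")
            for col, node in enumerate(graph.node_ids):
                vals = " ".join(f"{v:.12g}" for v in attrs.matrix[:, col])
                fh.write(f"{node} {vals}\n")
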