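"""Weighted protein-protein interaction networks and their graph Laplacians.

A network is read from a STRING-style links file (``protein1 protein2
combined_score``) into a :class:`PPINetwork` with a deterministic,
lexicographic node order, so that every downstream vector (heat, p-values,
enrichment profiles) is index-aligned and reproducible.  The graph Laplacian
``L = D - A`` generates the heat-diffusion semigroup ``exp(-L t)`` used by
:mod:`lhdnet.diffusion`.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import scipy.linalg
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components
from scipy.sparse.linalg import expm_multiply

__all__ = [
    "PPINetwork",
    "LaplacianOperator",
    "read_string_links",
    "build_laplacian",
    "component_labels",
    "StringParseError",
    "WEIGHT_MODES",
]

WEIGHT_MODES = ("scaled", "raw", "binary")

#: STRING combined confidence scores are integers on this closed range.
CONFIDENCE_MIN, CONFIDENCE_MAX = 1, 999


class StringParseError(ValueError):
    """Raised when a links file line cannot be interpreted."""


@dataclass(frozen=True)
class PPINetwork:
    """Undirected weighted network with integer confidence scores.

    Parameters
    ----------
    nodes
        Node identifiers in the canonical (lexicographically sorted) order.
        Vector indices throughout the package refer to this order.
    edges
        Mapping from an index pair ``(i, j)`` with ``i < j`` to the integer
        confidence score in ``[1, 999]``.
    """

    nodes: tuple[str, ...]
    edges: Mapping[tuple[int, int], int]
    index: Mapping[str, int] = field(repr=False, default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.index is None:
            object.__setattr__(
                self, "index", {name: i for i, name in enumerate(self.nodes)}
            )
        for (i, j), score in self.edges.items():
            if i == j:
                raise ValueError(f"self-loop on node {self.nodes[i]!r}")
            if not (i < j):
                raise ValueError(f"edge key ({i}, {j}) not in canonical i<j form")
            if not (CONFIDENCE_MIN <= int(score) <= CONFIDENCE_MAX):
                raise ValueError(f"confidence {score} outside [1, 999]")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def has_node(self, name: str) -> bool:
        return name in self.index

    def confidence(self, a: str, b: str) -> int:
        """Confidence of edge (a, b), or 0 if absent."""
        i, j = self.index[a], self.index[b]
        if i > j:
            i, j = j, i
        return int(self.edges.get((i, j), 0))

    def neighbors(self, name: str) -> dict[str, int]:
        """Neighbors of ``name`` mapped to edge confidence."""
        g = self.index[name]
        out: dict[str, int] = {}
        for (i, j), score in self.edges.items():
            if i == g:
                out[self.nodes[j]] = int(score)
            elif j == g:
                out[self.nodes[i]] = int(score)
        return out

    def adjacency(self, weight_mode: str = "scaled") -> sp.csr_array:
        """Symmetric adjacency under the given weight mode.

        ``scaled`` divides confidences by 1000 (weights in (0, 1)), ``raw``
        keeps the integer scores, ``binary`` sets every edge weight to 1.
        """
        if weight_mode not in WEIGHT_MODES:
            raise ValueError(
                f"unknown weight_mode {weight_mode!r}; expected one of {WEIGHT_MODES}"
            )
        n = self.n_nodes
        if not self.edges:
            return sp.csr_array((n, n))
        ii, jj, ss = [], [], []
        for (i, j), score in self.edges.items():
            ii.append(i)
            jj.append(j)
            ss.append(score)
        s = np.asarray(ss, dtype=float)
        if weight_mode == "scaled":
            w = s / 1000.0
        elif weight_mode == "raw":
            w = s
        else:
            w = np.ones_like(s)
        rows = np.concatenate([ii, jj])
        cols = np.concatenate([jj, ii])
        data = np.concatenate([w, w])
        return sp.csr_array((data, (rows, cols)), shape=(n, n))

    def to_links_lines(self) -> list[str]:
        """Render the network back to STRING-dialect lines (one per edge)."""
        lines = []
        for (i, j), score in sorted(self.edges.items()):
            lines.append(f"{self.nodes[i]} {self.nodes[j]} {int(score)}")
        return lines


def _open_text(path: Path):
    if str(path).endswith(".gz"):
        return io.TextIOWrapper(gzip.open(path, "rb"), encoding="utf-8")
    return open(path, "r", encoding="utf-8")


def read_string_links(path: str | Path, min_confidence: int = 1) -> PPINetwork:
    """Parse a STRING-style links file into a :class:`PPINetwork`.

    Lines are whitespace-separated triples ``protein1 protein2 score``; an
    optional single header line is skipped.  Duplicate directed records
    ``(a, b, s1)`` / ``(b, a, s2)`` collapse to one undirected edge keeping
    the maximum score.  Edges with score below ``min_confidence`` are
    dropped, but their endpoint nodes are retained (isolated), so the node
    universe — and hence vector indexing — depends only on the input file.

    Raises
    ------
    StringParseError
        On a malformed line (wrong field count, non-integer score, or score
        outside [1, 999]), naming the offending line number.
    ValueError
        If no edge survives ``min_confidence`` filtering.
    """
    path = Path(path)
    nodes: set[str] = set()
    best: dict[tuple[str, str], int] = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            fields = stripped.split()
            if lineno == 1 and _looks_like_header(fields):
                continue
            if len(fields) != 3:
                raise StringParseError(
                    f"{path.name}:{lineno}: expected 3 fields, got {len(fields)}"
                )
            a, b, raw_score = fields
            try:
                score = int(raw_score)
            except ValueError:
                raise StringParseError(
                    f"{path.name}:{lineno}: score {raw_score!r} is not an integer"
                ) from None
            if not (CONFIDENCE_MIN <= score <= CONFIDENCE_MAX):
                raise StringParseError(
                    f"{path.name}:{lineno}: score {score} outside [1, 999]"
                )
            if a == b:
                raise StringParseError(f"{path.name}:{lineno}: self-loop on {a!r}")
            nodes.add(a)
            nodes.add(b)
            key = (a, b) if a < b else (b, a)
            prev = best.get(key)
            if prev is None or score > prev:
                best[key] = score

    ordered = tuple(sorted(nodes))
    index = {name: i for i, name in enumerate(ordered)}
    edges = {
        (index[a], index[b]): score
        for (a, b), score in best.items()
        if score >= min_confidence
    }
    if not edges:
        raise ValueError(
            f"{path.name}: no edges remain at min_confidence={min_confidence}"
        )
    return PPINetwork(nodes=ordered, edges=edges)


def _looks_like_header(fields: Sequence[str]) -> bool:
    if len(fields) != 3:
        return True
    try:
        int(fields[2])
    except ValueError:
        return True
    return False


def network_from_edges(
    nodes: Iterable[str], edges: Mapping[tuple[str, str], int]
) -> PPINetwork:
    """Build a :class:`PPINetwork` from named edges (convenience constructor)."""
    ordered = tuple(sorted(set(nodes)))
    index = {name: i for i, name in enumerate(ordered)}
    indexed: dict[tuple[int, int], int] = {}
    for (a, b), score in edges.items():
        i, j = index[a], index[b]
        if i > j:
            i, j = j, i
        prev = indexed.get((i, j))
        if prev is None or score > prev:
            indexed[(i, j)] = int(score)
    return PPINetwork(nodes=ordered, edges=indexed)


#: Dense spectral path is used below this node count; above it, the action of
#: the matrix exponential is applied iteratively without densifying.
DENSE_SPECTRAL_LIMIT = 500


class LaplacianOperator:
    """Graph Laplacian ``L = D - A`` with the heat-kernel action ``exp(-L t)``.

    For networks below :data:`DENSE_SPECTRAL_LIMIT` nodes the operator
    eigendecomposes ``L`` once and applies ``exp(-lambda t)`` in the
    eigenbasis, which makes repeated propagations (permutation replicates)
    essentially free.  Larger networks use Krylov-based
    ``expm_multiply`` on the sparse ``L`` so the dense exponential is never
    materialized.

    Attributes
    ----------
    n_apply_calls
        Instrumentation counter: number of ``apply_exp_neg`` evaluations.
    """

    def __init__(self, net: PPINetwork, weight_mode: str = "scaled") -> None:
        if net.n_nodes == 0:
            raise ValueError("cannot build a Laplacian for an empty network")
        self.weight_mode = weight_mode
        self.adjacency = net.adjacency(weight_mode)
        self.degrees = np.asarray(self.adjacency.sum(axis=1)).ravel()
        self.laplacian = sp.dia_array(
            (self.degrees[np.newaxis, :], [0]), shape=self.adjacency.shape
        ).tocsr() - self.adjacency
        self.dimension = net.n_nodes
        self.n_apply_calls = 0
        self._eigvals: np.ndarray | None = None
        self._eigvecs: np.ndarray | None = None

    def _ensure_spectral(self) -> None:
        if self._eigvals is None:
            dense = self.laplacian.toarray()
            self._eigvals, self._eigvecs = scipy.linalg.eigh(dense)

    def apply_exp_neg(self, h: np.ndarray, t: float) -> np.ndarray:
        """Return ``h @ exp(-L t)`` (equals ``exp(-L t) @ h``; L symmetric)."""
        if t < 0:
            raise ValueError(f"diffusion time must be nonnegative, got {t}")
        h = np.asarray(h, dtype=float)
        if h.shape != (self.dimension,):
            raise ValueError(
                f"heat vector has shape {h.shape}, operator dimension {self.dimension}"
            )
        self.n_apply_calls += 1
        if t == 0:
            return h.copy()
        if self.dimension < DENSE_SPECTRAL_LIMIT:
            self._ensure_spectral()
            coeffs = self._eigvecs.T @ h
            decay = np.exp(-np.clip(self._eigvals, 0.0, None) * t)
            return self._eigvecs @ (decay * coeffs)
        return expm_multiply(-self.laplacian * t, h)

    def check_invariants(self, rtol: float = 1e-10) -> None:
        """Assert symmetry and zero row sums of L (diagnostic helper)."""
        row_sums = np.asarray(self.laplacian.sum(axis=1)).ravel()
        scale = max(1.0, float(np.abs(self.degrees).max(initial=0.0)))
        if np.abs(row_sums).max(initial=0.0) > rtol * scale:
            raise AssertionError("Laplacian row sums deviate from zero")
        asym = (self.laplacian - self.laplacian.T).toarray()
        if np.abs(asym).max(initial=0.0) > rtol * scale:
            raise AssertionError("Laplacian is not symmetric")


def build_laplacian(net: PPINetwork, weight_mode: str = "scaled") -> LaplacianOperator:
    """Construct the Laplacian operator for ``net`` under ``weight_mode``."""
    if weight_mode not in WEIGHT_MODES:
        raise ValueError(
            f"unknown weight_mode {weight_mode!r}; expected one of {WEIGHT_MODES}"
        )
    return LaplacianOperator(net, weight_mode)


def component_labels(net: PPINetwork) -> np.ndarray:
    """Connected-component id per node, aligned with ``net.nodes``."""
    if net.n_nodes == 0:
        raise ValueError("empty network")
    adj = net.adjacency("binary")
    _, labels = connected_components(adj, directed=False)
    return labels


def network_summary(net: PPINetwork) -> dict[str, int]:
    """Node/edge/component counts, logged after parsing."""
    labels = component_labels(net)
    return {
        "node_count": net.n_nodes,
        "edge_count": net.n_edges,
        "components": int(labels.max(initial=0)) + 1,
    }
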