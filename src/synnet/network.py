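"""Undirected word-type networks built from dependency treebanks.

Each dependency row (dependent, governor) becomes an unordered edge between
the two word types; repeated pairs are merged into a single edge whose
multiplicity counts the collapsed instances. Root rows contribute the
dependent as an isolated vertex but no edge; self-pairs are dropped. All
metric computation treats the result as a simple graph.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Iterator

import numpy as np
from scipy import sparse

from synnet.errors import ValidationError
from synnet.treebank import Treebank


def _edge_key(u: str, v: str) -> tuple[str, str]:
    return (u, v) if u <= v else (v, u)


class SyntacticNetwork:
    """Simple undirected graph over word types with edge multiplicities.

    Vertex order is insertion order, which makes exports and reports stable
    across runs for the same input.
    """

    def __init__(self) -> None:
        self._adj: dict[str, set[str]] = {}
        self._mult: dict[tuple[str, str], int] = {}

    # -- construction -------------------------------------------------------

    def add_vertex(self, v: str) -> None:
        if v not in self._adj:
            self._adj[v] = set()

    def add_edge(self, u: str, v: str, count: int = 1) -> None:
        if u == v:
            raise ValidationError(f"self-loop on {u!r} not allowed")
        if count < 1:
            raise ValidationError("edge count must be positive")
        self.add_vertex(u)
        self.add_vertex(v)
        self._adj[u].add(v)
        self._adj[v].add(u)
        key = _edge_key(u, v)
        self._mult[key] = self._mult.get(key, 0) + count

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str]],
        vertices: Iterable[str] = (),
    ) -> "SyntacticNetwork":
        net = cls()
        for v in vertices:
            net.add_vertex(str(v))
        for u, v in edges:
            net.add_edge(str(u), str(v))
        return net

    # -- inspection ---------------------------------------------------------

    @property
    def vertices(self) -> list[str]:
        return list(self._adj)

    @property
    def N(self) -> int:
        return len(self._adj)

    @property
    def M(self) -> int:
        return len(self._mult)

    def __contains__(self, v: str) -> bool:
        return v in self._adj

    def has_edge(self, u: str, v: str) -> bool:
        return _edge_key(u, v) in self._mult

    def multiplicity(self, u: str, v: str) -> int:
        return self._mult.get(_edge_key(u, v), 0)

    def neighbors(self, v: str) -> set[str]:
        return set(self._adj[v])

    def degree(self, v: str) -> int:
        return len(self._adj[v])

    def degrees(self) -> dict[str, int]:
        return {v: len(nbrs) for v, nbrs in self._adj.items()}

    def edges(self) -> Iterator[tuple[tuple[str, str], int]]:
        """Yield ((u, v), multiplicity) with u, v in sorted order per edge."""
        yield from self._mult.items()

    def total_multiplicity(self) -> int:
        return sum(self._mult.values())

    def adjacency_matrix(self) -> tuple[sparse.csr_matrix, list[str]]:
        """Binary CSR adjacency matrix plus the vertex order it indexes."""
        order = self.vertices
        index = {v: i for i, v in enumerate(order)}
        rows: list[int] = []
        cols: list[int] = []
        for (u, v) in self._mult:
            i, j = index[u], index[v]
            rows.extend((i, j))
            cols.extend((j, i))
        data = np.ones(len(rows), dtype=np.int8)
        mat = sparse.csr_matrix(
            (data, (rows, cols)), shape=(self.N, self.N), dtype=np.int8
        )
        return mat, order

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SyntacticNetwork):
            return NotImplemented
        return set(self._adj) == set(other._adj) and self._mult == other._mult

    def __repr__(self) -> str:
        return f"SyntacticNetwork(N={self.N}, M={self.M})"


def build_network(
    treebank: Treebank,
    *,
    drop_punct: bool = True,
    key_by_pos: bool = False,
) -> SyntacticNetwork:
    """Build the undirected word-type network of a whole treebank.

    Parameters
    ----------
    treebank:
        Validated input corpus; must be non-empty.
    drop_punct:
        Skip dependency rows where either endpoint is punctuation, and never
        create punctuation vertices (corpora annotated without punctuation
        are unaffected).
    key_by_pos:
        Key vertices by ``form/POS`` instead of bare surface form
        (off-default diagnostic mode).

    The returned network carries a ``build_log`` dict with counts of dropped
    self-loops, dropped punctuation rows and multi-root sentences.

    Raises
    ------
    ValidationError
        If the treebank is empty or yields no edges at all.
    """
    if len(treebank) == 0:
        raise ValidationError("cannot build a network from an empty treebank")

    def key(tok) -> str:
        return f"{tok.form}/{tok.pos}" if key_by_pos else tok.form

    net = SyntacticNetwork()
    dropped_self_loops = 0
    dropped_punct = 0
    multi_root = 0
    for sent in treebank:
        if sent.root_count > 1:
            multi_root += 1
        for tok in sent:
            if tok.is_root:
                if not (tok.is_punct and drop_punct):
                    net.add_vertex(key(tok))
                continue
            gov = sent.governor_of(tok)
            if drop_punct and (tok.is_punct or gov.is_punct):
                dropped_punct += 1
                continue
            u, v = key(tok), key(gov)
            if u == v:
                dropped_self_loops += 1
                net.add_vertex(u)
                continue
            net.add_edge(u, v)
    if net.M == 0:
        raise ValidationError("treebank produced no edges")
    net.build_log = {  # type: ignore[attr-defined]
        "dropped_self_loops": dropped_self_loops,
        "dropped_punctuation": dropped_punct,
        "multi_root_sentences": multi_root,
        "vertices": net.N,
        "edges": net.M,
        "dependency_instances": net.total_multiplicity(),
    }
    return net


def top_hubs(
    network: SyntacticNetwork, n: int
) -> list[tuple[str, int, float]]:
    """Rank vertices by degree (ties broken lexicographically).

    Returns up to ``n`` tuples of (word type, degree, degree share), where
    degree share is the vertex degree divided by the total degree sum 2M.
    """
    if network.N == 0:
        raise ValidationError("network is empty")
    if n < 1:
        raise ValidationError("n must be >= 1")
    if n > network.N:
        warnings.warn(
            f"requested {n} hubs but network has only {network.N} vertices",
            stacklevel=2,
        )
        n = network.N
    degs = network.degrees()
    total = sum(degs.values())
    ranked = sorted(degs.items(), key=lambda kv: (-kv[1], kv[0]))
    return [
        (v, d, d / total if total else 0.0) for v, d in ranked[:n]
    ]
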