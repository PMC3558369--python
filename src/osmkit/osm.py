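"""Lifting substitution types to whole alignment columns and the OSM matrix.

A group element σ_i acting on the pendant edge of taxon j lifts to the
character space C^n as the Kronecker product with σ_i in position j and
the identity elsewhere.  On an internal edge it acts simultaneously on
every descendant taxon, which equals the product of the pendant lifts of
its descendants.  The set Σ^T of all (edge, non-identity type) operators
generates the full group Σ^n on characters; its Cayley graph distance is
the minimal number of single substitutions separating two columns.

The OSM (one-step mutation) matrix is the convex combination of the Σ^T
operators weighted by relative branch length p_e and substitution-type
probability α_{e,i}; it is doubly stochastic and describes one random
substitution somewhere on the tree.

Characters of length n over r states are indexed in mixed radix with
taxon 1 most significant: index(f) = Σ_j index(f_j) · r^(n-1-j).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import scipy.sparse as sp

from .groups import Alphabet, GroupAction, Permutation
from .phylo import EdgeWeights, RootedTree, as_state_string

__all__ = [
    "DENSE_GUARD",
    "INDEX_GUARD",
    "EdgeOperator",
    "OSMMatrix",
    "char_index",
    "index_to_char",
    "lift_to_edge",
    "build_sigma_T",
    "build_osm",
    "min_power_positive",
    "cayley_shortest_path",
    "build_cayley_graph",
    "stationary_check",
]

#: Largest character-space size for which index maps are materialized.
INDEX_GUARD = 65536
#: Largest character-space size for which dense matrices are materialized.
DENSE_GUARD = 4096


def char_index(f: str, alphabet: Alphabet) -> int:
    idx = 0
    for c in f:
        idx = idx * alphabet.size + alphabet.index(c)
    return idx


def index_to_char(idx: int, n: int, alphabet: Alphabet) -> str:
    r = alphabet.size
    out = []
    for _ in range(n):
        idx, d = divmod(idx, r)
        out.append(alphabet.letters[d])
    return "".join(reversed(out))


class EdgeOperator:
    """A group element lifted to character space along one tree edge.

    Applies σ_i at every descendant taxon of the edge and the identity
    elsewhere.  Stored implicitly (edge, element, descendant positions);
    index maps and matrices are materialized only on request and only
    below the configured guards.
    """

    def __init__(self, tree: RootedTree, group: GroupAction, edge: str, element: Permutation):
        self.tree = tree
        self.group = group
        self.edge = edge
        self.element = element
        self.element_index = group.index_of(element)
        self.positions = tuple(tree.taxon_index(x) for x in tree.descendants(edge))
        self.r = group.alphabet.size
        self.n = tree.n_leaves

    @property
    def label(self) -> str:
        return f"{self.edge}:{self.element.label}"

    def apply_character(self, f: str) -> str:
        out = list(f)
        alpha = self.group.alphabet
        for j in self.positions:
            out[j] = self.element.apply_letter(alpha, out[j])
        return "".join(out)

    def apply_indices(self, idx: np.ndarray) -> np.ndarray:
        """Vectorized action on character indices."""
        idx = np.asarray(idx, dtype=np.int64)
        perm = np.asarray(self.element.mapping, dtype=np.int64)
        r, n = self.r, self.n
        out = idx.copy()
        for j in self.positions:
            place = r ** (n - 1 - j)
            digit = (out // place) % r
            out += (perm[digit] - digit) * place
        return out

    def index_map(self, guard: int = INDEX_GUARD) -> np.ndarray:
        """The full permutation of character space as a target-index vector."""
        size = self.r ** self.n
        if size > guard:
            raise ValueError(
                f"character space of size {self.r}^{self.n} exceeds the guard ({guard}); "
                "apply the operator lazily instead of materializing it")
        return self.apply_indices(np.arange(size, dtype=np.int64))

    def matrix(self, guard: int = DENSE_GUARD, sparse: bool = True):
        """The operator as an r^n × r^n permutation matrix (sources on rows)."""
        size = self.r ** self.n
        if size > guard:
            raise ValueError(
                f"character space of size {self.r}^{self.n} exceeds the guard ({guard})")
        targets = self.index_map(guard=max(guard, INDEX_GUARD))
        m = sp.csr_matrix(
            (np.ones(size), (np.arange(size), targets)), shape=(size, size))
        return m if sparse else m.toarray()

    def __repr__(self) -> str:
        return f"EdgeOperator({self.label}, n={self.n}, r={self.r})"


def lift_to_edge(t: RootedTree, g: GroupAction, edge: str, element) -> EdgeOperator:
    """Lift a non-identity group element to an edge of the tree.

    ``element`` may be a :class:`Permutation`, a label, or an element
    index 1..r-1.  The identity is rejected: the OSM sum runs over the
    non-identity types only, and lifting it would be a no-op.
    """
    if isinstance(element, int):
        element = g[element]
    elif isinstance(element, str):
        element = g.element(element)
    if element not in g:
        raise ValueError(f"element {element.label!r} is not in group {g.name}")
    if element.is_identity:
        raise ValueError("refusing to lift the identity; substitution types are the "
                         "non-identity elements")
    t.edge_child(edge)  # raises on unknown edge
    return EdgeOperator(t, g, edge, element)


def build_sigma_T(t: RootedTree, g: GroupAction) -> list:
    """All |E(T)|·(r-1) lifted operators: each edge × each non-identity type."""
    return [EdgeOperator(t, g, e, s) for e in t.edges for s in g.elements[1:]]


@dataclass
class OSMMatrix:
    """The one-step mutation matrix with its (edge, type) weight decomposition.

    ``terms`` lists ``(edge, element_label, element_index, weight)`` with
    weight = α_{e,i}·p_e; their weighted permutations sum to ``matrix``,
    which is doubly stochastic.
    """

    matrix: sp.csr_matrix
    terms: list
    tree: RootedTree
    group: GroupAction
    operators: list = field(repr=False, default_factory=list)

    @property
    def size(self) -> int:
        return self.matrix.shape[0]

    def entry(self, f, fd) -> float:
        a = self.group.alphabet
        i = char_index(as_state_string(f, self.tree), a)
        j = char_index(as_state_string(fd, self.tree), a)
        return float(self.matrix[i, j])

    def is_doubly_stochastic(self, tol: float = 1e-12) -> bool:
        rows = np.asarray(self.matrix.sum(axis=1)).ravel()
        cols = np.asarray(self.matrix.sum(axis=0)).ravel()
        return bool(np.abs(rows - 1).max() < tol and np.abs(cols - 1).max() < tol)

    def to_mtx(self, path) -> None:
        from scipy.io import mmwrite

        mmwrite(path, self.matrix.tocoo())

    def decomposition_tsv(self) -> str:
        lines = ["edge\ttype\tweight"]
        for edge, label, _, w in self.terms:
            lines.append(f"{edge}\t{label}\t{w:.12g}")
        return "\n".join(lines) + "\n"


def build_osm(t: RootedTree, g: GroupAction, w: EdgeWeights,
              guard: int = INDEX_GUARD) -> OSMMatrix:
    """Assemble the OSM matrix Σ_e Σ_i α_{e,i} p_e σ^{e,i} as a sparse operator."""
    w.validate()
    if w.n_types != g.size - 1:
        raise ValueError(f"weights carry {w.n_types} substitution types but the group "
                         f"has {g.size - 1}")
    size = g.alphabet.size ** t.n_leaves
    if size > guard:
        raise ValueError(f"character space of size {size} exceeds the guard ({guard})")
    rows = np.arange(size, dtype=np.int64)
    acc = sp.csr_matrix((size, size))
    terms, operators = [], []
    for e in t.edges:
        for i in range(1, g.size):
            op = EdgeOperator(t, g, e, g[i])
            weight = w.weight(e, i)
            targets = op.index_map(guard=guard)
            acc = acc + sp.csr_matrix(
                (np.full(size, weight), (rows, targets)), shape=(size, size))
            terms.append((e, g[i].label, i, weight))
            operators.append(op)
    return OSMMatrix(acc.tocsr(), terms, t, g, operators)


def min_power_positive(m: OSMMatrix, f, fd, max_k: int | None = None) -> int:
    """Smallest k with (M^k)[f, fd] > 0; equals the Cayley graph distance.

    Requires every (edge, type) weight to be strictly positive — with
    zero weights the support of powers of M and reachability in the
    Cayley graph would differ, and the two notions silently disagree.
    """
    if any(wt <= 0 for *_unused, wt in m.terms):
        raise ValueError("min_power_positive requires strictly positive edge/type weights")
    a = m.group.alphabet
    i = char_index(as_state_string(f, m.tree), a)
    j = char_index(as_state_string(fd, m.tree), a)
    if max_k is None:
        max_k = m.size
    v = np.zeros(m.size)
    v[i] = 1.0
    for k in range(max_k + 1):
        if v[j] > 0:
            return k
        v = m.matrix.T @ v
    raise RuntimeError(f"no positive entry within {max_k} powers")


def _generator_maps(t: RootedTree, g: GroupAction, guard: int) -> list:
    ops = build_sigma_T(t, g)
    return [(op.label, op.index_map(guard=guard)) for op in ops]


def cayley_shortest_path(t: RootedTree, g: GroupAction, f, fd,
                         guard: int = INDEX_GUARD) -> tuple:
    """BFS distance and one witness generator path from f to fd in the Cayley graph.

    Returns ``(length, [operator labels])``.  The generator set Σ^T is
    closed under inversion (C6), so the graph is undirected and the
    distance symmetric.
    """
    a = g.alphabet
    size = a.size ** t.n_leaves
    if size > guard:
        raise ValueError(f"character space of size {size} exceeds the BFS guard ({guard})")
    src = char_index(as_state_string(f, t), a)
    dst = char_index(as_state_string(fd, t), a)
    if src == dst:
        return 0, []
    gens = _generator_maps(t, g, guard)
    prev = np.full(size, -1, dtype=np.int64)       # predecessor vertex
    via = np.full(size, -1, dtype=np.int64)        # generator used to reach
    prev[src] = src
    frontier = np.array([src], dtype=np.int64)
    while frontier.size and prev[dst] < 0:
        nxt_level = []
        for gi, (_, gmap) in enumerate(gens):
            nxt = gmap[frontier]
            mask = prev[nxt] < 0
            nxt_f, src_f = nxt[mask], frontier[mask]
            # keep first occurrence per target
            uniq, first = np.unique(nxt_f, return_index=True)
            prev[uniq] = src_f[first]
            via[uniq] = gi
            nxt_level.append(uniq)
        frontier = np.unique(np.concatenate(nxt_level)) if nxt_level else np.array([], dtype=np.int64)
    if prev[dst] < 0:
        raise RuntimeError("target not reachable; Σ^T should generate the full group")
    path = []
    v = dst
    while v != src:
        path.append(gens[via[v]][0])
        v = prev[v]
    path.reverse()
    return len(path), path


def build_cayley_graph(t: RootedTree, g: GroupAction, guard: int = DENSE_GUARD) -> nx.MultiGraph:
    """The explicit Cayley graph on character strings with generator-labelled edges."""
    a = g.alphabet
    size = a.size ** t.n_leaves
    if size > guard:
        raise ValueError(f"character space of size {size} exceeds the guard ({guard})")
    graph = nx.MultiGraph()
    chars = [index_to_char(i, t.n_leaves, a) for i in range(size)]
    graph.add_nodes_from(chars)
    for op in build_sigma_T(t, g):
        gmap = op.index_map(guard=guard)
        for i in range(size):
            j = int(gmap[i])
            if i <= j:  # one undirected edge per unordered pair per generator
                graph.add_edge(chars[i], chars[j], generator=op.label)
    return graph


def cayley_edge_list_tsv(graph: nx.MultiGraph) -> str:
    """Export a Cayley graph as a TSV edge list with generator labels."""
    lines = ["from\tto\tgenerator"]
    for u, v, data in graph.edges(data=True):
        lines.append(f"{u}\t{v}\t{data.get('generator', '')}")
    return "\n".join(lines) + "\n"


def stationary_check(m: OSMMatrix, steps: int = 200, tol: float = 1e-6,
                     start=None) -> dict:
    """Verify the uniform distribution is stationary and attracts a point mass.

    Double stochasticity makes the uniform vector exactly stationary; with
    strictly positive weights the chain is irreducible and aperiodic on
    the character space, so repeated application to any start approaches
    uniform.  Non-convergence is reported, not raised.
    """
    size = m.size
    uniform = np.full(size, 1.0 / size)
    fixed_dev = float(np.abs(m.matrix.T @ uniform - uniform).max())
    if start is None:
        v = np.zeros(size)
        v[0] = 1.0
    else:
        v = np.zeros(size)
        v[char_index(as_state_string(start, m.tree), m.group.alphabet)] = 1.0
    for _ in range(steps):
        v = m.matrix.T @ v
    final_dev = float(np.abs(v - uniform).max())
    return {
        "uniform_is_fixed": fixed_dev < 1e-12,
        "uniform_fixed_deviation": fixed_dev,
        "power_deviation": final_dev,
        "converged": final_dev < tol,
        "steps": steps,
    }
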