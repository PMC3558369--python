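"""Rooted binary phylogenetic X-trees with a degree-1 root.

The root ρ has indegree 0 and outdegree 1: its single outgoing edge (the
"stem") sits above the rest of the tree, so that a substitution on it
affects every taxon.  Standard newick writers emit bifurcating roots, so
the default parsing policy prepends a stem edge and a degree-1 root when
needed.

Edges are identified by their child vertex: pendant edges by the taxon
label (``e_1``), internal edges by the concatenated sorted descendant
taxa (``e_12``), the stem edge by all taxa.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import dendropy
import numpy as np

__all__ = [
    "RootedTree",
    "EdgeWeights",
    "Character",
    "parse_newick",
    "descendants",
    "normalize_weights",
]


class RootedTree:
    """A rooted binary phylogenetic tree on named taxa, edges directed away from the root.

    Vertices are referred to by name: leaves by their taxon label, internal
    vertices by the sorted concatenation of their descendant taxa, the root
    by ``"rho"``.  ``taxon_order`` fixes the position of each taxon in
    whole-tree character vectors and Kronecker lifts (taxon 1 leftmost /
    most significant); it defaults to the left-to-right leaf order of the
    newick string.
    """

    def __init__(self, children: dict, lengths: dict, taxon_order: tuple):
        self.children = children          # vertex -> tuple of child vertices
        self.taxon_order = tuple(taxon_order)
        self.root = "rho"
        parent = {}
        for v, kids in children.items():
            for c in kids:
                parent[c] = v
        self.parent = parent
        self._taxon_pos = {t: i for i, t in enumerate(self.taxon_order)}
        # preorder edge list (parent before child)
        order = []
        stack = [self.root]
        while stack:
            v = stack.pop()
            kids = children.get(v, ())
            order.extend(kids)
            stack.extend(reversed(kids))
        self._edge_children = order  # child vertices, preorder
        self.edges = tuple(f"e_{c}" for c in order)
        self._child_of_edge = {f"e_{c}": c for c in order}
        # descendant taxa per vertex
        desc: dict[str, tuple] = {}
        for c in reversed(order):
            kids = children.get(c, ())
            if not kids:
                desc[c] = (c,)
            else:
                desc[c] = tuple(sorted((t for k in kids for t in desc[k]),
                                       key=self._taxon_pos.get))
        self._desc = desc
        self.lengths = {e: lengths.get(e) for e in self.edges}

    # -- structure ---------------------------------------------------------

    @property
    def n_leaves(self) -> int:
        return len(self.taxon_order)

    @property
    def stem_edge(self) -> str:
        return self.edges[0]

    def is_leaf(self, vertex: str) -> bool:
        return not self.children.get(vertex)

    def leaf_edges(self) -> tuple:
        return tuple(e for e in self.edges if self.is_leaf(self._child_of_edge[e]))

    def internal_edges(self) -> tuple:
        return tuple(e for e in self.edges if not self.is_leaf(self._child_of_edge[e]))

    def edge_child(self, edge: str) -> str:
        try:
            return self._child_of_edge[edge]
        except KeyError:
            raise KeyError(f"unknown edge {edge!r}; edges are {self.edges}") from None

    def child_edges(self, edge: str) -> tuple:
        v = self.edge_child(edge)
        return tuple(f"e_{c}" for c in self.children.get(v, ()))

    def descendants(self, edge: str) -> tuple:
        """All taxa whose path to the root passes ``edge`` (in taxon order)."""
        return self._desc[self.edge_child(edge)]

    def taxon_index(self, taxon: str) -> int:
        return self._taxon_pos[taxon]

    # -- IO ----------------------------------------------------------------

    def to_newick(self, include_lengths: bool = True) -> str:
        def render(v: str) -> str:
            kids = self.children.get(v, ())
            if not kids:
                s = v
            else:
                s = "(" + ",".join(render(c) for c in kids) + ")"
            ln = self.lengths.get(f"e_{v}")
            if include_lengths and ln is not None:
                s += f":{ln:g}"
            return s

        top = self.children[self.root][0]
        return f"({render(top)});"

    def __repr__(self) -> str:
        return f"RootedTree({self.to_newick(include_lengths=False)!r}, n={self.n_leaves})"


def _vertex_name(taxa: tuple) -> str:
    if all(len(t) == 1 for t in taxa):
        return "".join(sorted(taxa))
    return ",".join(sorted(taxa))


def parse_newick(text: str, stem_policy: str = "add_stem",
                 stem_length: float | None = None,
                 taxon_order: tuple | None = None) -> RootedTree:
    """Read a rooted binary tree from newick, ensuring a degree-1 root.

    If the newick root already has a single child it serves as ρ directly;
    if it bifurcates and ``stem_policy`` is ``"add_stem"`` (default), a stem
    edge of length ``stem_length`` is prepended.  Non-binary vertices and
    duplicate leaf labels are rejected.
    """
    try:
        dtree = dendropy.Tree.get(data=text, schema="newick", rooting="force-rooted",
                                  preserve_underscores=True,
                                  suppress_internal_node_taxa=True)
    except dendropy.dataio.newickreader.NewickReader.NewickReaderDuplicateTaxonError as exc:
        raise ValueError(f"duplicate leaf names in newick input: {exc}") from exc

    def leaf_label(node) -> str:
        return node.taxon.label if node.taxon is not None else (node.label or "")

    # left-to-right leaves, respecting newick child order
    leaves: list[str] = []

    def walk(node):
        kids = node.child_nodes()
        if not kids:
            label = leaf_label(node)
            if not label:
                raise ValueError("unnamed leaf in newick input")
            leaves.append(label)
        for k in kids:
            walk(k)

    walk(dtree.seed_node)
    if len(set(leaves)) != len(leaves):
        dup = sorted({x for x in leaves if leaves.count(x) > 1})
        raise ValueError(f"duplicate leaf names: {dup}")
    order = tuple(taxon_order) if taxon_order is not None else tuple(leaves)
    if set(order) != set(leaves):
        raise ValueError("taxon_order does not match the leaf set")
    pos = {t: i for i, t in enumerate(order)}

    children: dict[str, tuple] = {}
    lengths: dict[str, float] = {}

    def build(node) -> str:
        kids = node.child_nodes()
        if not kids:
            name = leaf_label(node)
        elif len(kids) == 2:
            names = [build(k) for k in kids]
            taxa = tuple(sorted((t for k in names for t in _taxa_of[k]), key=pos.get))
            name = _vertex_name(taxa)
            children[name] = tuple(names)
            _taxa_of[name] = taxa
        else:
            raise ValueError(f"non-binary vertex with {len(kids)} children")
        if not node.child_nodes():
            _taxa_of[name] = (name,)
        if node.edge.length is not None:
            lengths[f"e_{name}"] = float(node.edge.length)
        return name

    _taxa_of: dict[str, tuple] = {}
    seed = dtree.seed_node
    seed_kids = seed.child_nodes()
    if len(seed_kids) == 1:
        top = build(seed_kids[0])
        if seed_kids[0].edge.length is not None:
            lengths[f"e_{top}"] = float(seed_kids[0].edge.length)
    elif len(seed_kids) == 2:
        if stem_policy != "add_stem":
            raise ValueError("newick root bifurcates; pass stem_policy='add_stem' "
                             "to prepend a degree-1 root")
        top = build(seed)
        if stem_length is not None:
            lengths[f"e_{top}"] = float(stem_length)
    elif len(seed_kids) == 0:
        raise ValueError("newick input has no leaves below the root")
    else:
        raise ValueError(f"non-binary root with {len(seed_kids)} children")
    children["rho"] = (top,)
    return RootedTree(children, lengths, order)


def descendants(t: RootedTree, edge: str) -> tuple:
    """Module-level alias for :meth:`RootedTree.descendants`."""
    return t.descendants(edge)


# ---------------------------------------------------------------------------
# weights


@dataclass
class EdgeWeights:
    """Relative branch lengths p_e and per-edge substitution-type probabilities.

    ``p[e]`` is edge ``e``'s share of total tree length — the probability
    that a single substitution, given that one occurred somewhere on the
    tree, occurred on ``e``; the p_e sum to 1.  ``alpha[e][i-1]`` is the
    probability that a substitution on ``e`` is of (non-identity) type
    ``i``; each row sums to 1.
    """

    p: dict
    alpha: dict

    @property
    def n_types(self) -> int:
        return len(next(iter(self.alpha.values())))

    def validate(self, tol: float = 1e-9) -> None:
        total = sum(self.p.values())
        if abs(total - 1.0) > tol:
            raise ValueError(f"edge probabilities sum to {total}, not 1")
        if any(v < 0 for v in self.p.values()):
            raise ValueError("negative edge probability")
        for e, row in self.alpha.items():
            row = np.asarray(row, dtype=float)
            if row.min() < 0 or abs(row.sum() - 1.0) > tol:
                raise ValueError(f"type probabilities on edge {e} do not form a distribution")

    def weight(self, edge: str, i: int) -> float:
        """alpha_{e,i} * p_e for non-identity type index i (1-based)."""
        return float(self.alpha[edge][i - 1]) * float(self.p[edge])

    @property
    def all_positive(self) -> bool:
        return all(v > 0 for v in self.p.values()) and all(
            np.asarray(row).min() > 0 for row in self.alpha.values())


def normalize_weights(t: RootedTree, n_types: int, lengths: dict | None = None,
                      uniform: bool = False, alpha: dict | None = None) -> EdgeWeights:
    """Build normalized :class:`EdgeWeights` from branch lengths or uniformly.

    With ``uniform=True`` every edge gets ``1/|E|``.  Otherwise lengths are
    taken from ``lengths`` (edge id -> value) or the tree's own branch
    lengths (missing values count as 0, which is the natural reading for a
    synthetic stem edge) and scaled to sum to 1.  Substitution-type
    probabilities default to the uniform ``1/(r-1)`` per non-identity type.
    """
    if n_types < 1:
        raise ValueError("need at least one non-identity substitution type")
    if uniform:
        m = len(t.edges)
        p = {e: 1.0 / m for e in t.edges}
    else:
        src = lengths if lengths is not None else t.lengths
        vals = {e: float(src.get(e) or 0.0) for e in t.edges}
        if any(v < 0 for v in vals.values()):
            raise ValueError("negative branch length")
        total = sum(vals.values())
        if total <= 0:
            raise ValueError("all branch lengths are zero; pass uniform=True instead")
        p = {e: v / total for e, v in vals.items()}
    if alpha is None:
        alpha = {e: np.full(n_types, 1.0 / n_types) for e in t.edges}
    else:
        alpha = {e: np.asarray(alpha[e], dtype=float) for e in t.edges}
    w = EdgeWeights(p, alpha)
    w.validate()
    return w


# ---------------------------------------------------------------------------
# characters


@dataclass(frozen=True)
class Character:
    """An alignment column: one state per taxon.

    May be free-standing (``taxa=None``, letters aligned positionally to a
    tree's taxon order) or carry taxon names, in which case alignment to a
    tree matches by name rather than by position.
    """

    letters: tuple
    taxa: tuple | None = None

    @classmethod
    def from_string(cls, s: str, taxa=None) -> "Character":
        return cls(tuple(s), tuple(taxa) if taxa is not None else None)

    @classmethod
    def from_tsv(cls, text: str) -> "Character":
        """Two-column TSV: taxon <tab> state, one row per taxon."""
        taxa, letters = [], []
        for line in text.strip().splitlines():
            if not line.strip() or line.startswith("#"):
                continue
            taxon, letter = line.split("\t")
            taxa.append(taxon.strip())
            letters.append(letter.strip())
        return cls(tuple(letters), tuple(taxa))

    @classmethod
    def from_fasta_column(cls, fasta_text: str, column: int) -> "Character":
        """One alignment column (0-based) of a FASTA alignment."""
        from Bio import SeqIO

        taxa, letters = [], []
        for rec in SeqIO.parse(io.StringIO(fasta_text), "fasta"):
            taxa.append(rec.id)
            letters.append(str(rec.seq)[column])
        return cls(tuple(letters), tuple(taxa))

    def __len__(self) -> int:
        return len(self.letters)

    def __str__(self) -> str:
        return "".join(self.letters)

    def align_to(self, t: RootedTree) -> str:
        """The state string in the tree's taxon order."""
        if self.taxa is None:
            if len(self.letters) != t.n_leaves:
                raise ValueError(f"character length {len(self.letters)} != {t.n_leaves} taxa")
            return "".join(self.letters)
        by_name = dict(zip(self.taxa, self.letters))
        missing = [x for x in t.taxon_order if x not in by_name]
        if missing:
            raise ValueError(f"character lacks states for taxa {missing}")
        return "".join(by_name[x] for x in t.taxon_order)


def as_state_string(f, t: RootedTree) -> str:
    """Coerce a character given as str or :class:`Character` into tree taxon order."""
    if isinstance(f, Character):
        return f.align_to(t)
    f = str(f)
    if len(f) != t.n_leaves:
        raise ValueError(f"character length {len(f)} != {t.n_leaves} taxa")
    return f
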