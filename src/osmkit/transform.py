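"""Minimal substitution counts between alignment columns on a tree.

Given a rooted binary tree, an admissible group Σ of substitution types
and two columns f, f^d, the minimal number of single substitutions (one
group element applied on one edge each) needed to turn f into f^d is
computed in three steps:

1. regularity gives a unique per-position operation σ̂ with σ̂(f) = f^d;
2. σ̂ applied to a constant column c1...c1 yields a column h, and by
   commutativity any edge-assignment transforming f to f^d also evolves
   c1...c1 into h;
3. the parsimony score of h with the root state fixed to c1 is exactly
   the minimal number of edges that must carry a substitution.

The score is linear in the number of taxa via the Fitch pass, while the
search space it summarizes grows like r^n.  An independent breadth-first
oracle over generator compositions is provided for cross-validation.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

from .groups import GroupAction
from .phylo import RootedTree, as_state_string

__all__ = [
    "PositionwiseOperation",
    "FitchResult",
    "positionwise_sigma",
    "apply_to_constant",
    "fitch_rooted",
    "min_substitutions",
    "exhaustive_oracle",
]


@dataclass(frozen=True)
class PositionwiseOperation:
    """One group element per taxon, acting elementwise on characters."""

    elements: tuple
    group: GroupAction

    @property
    def labels(self) -> tuple:
        return tuple(p.label for p in self.elements)

    def apply(self, f) -> str:
        a = self.group.alphabet
        f = str(f)
        if len(f) != len(self.elements):
            raise ValueError("character length does not match operation length")
        return "".join(p.apply_letter(a, c) for p, c in zip(self.elements, f))

    def __len__(self) -> int:
        return len(self.elements)

    def __str__(self) -> str:
        return "(" + ",".join(self.labels) + ")"


def positionwise_sigma(g: GroupAction, f, fd) -> PositionwiseOperation:
    """The unique elementwise operation σ̂ with σ̂(f) = f^d.

    Position by position, regularity (C2) provides exactly one substitution
    type carrying f_j onto f^d_j.
    """
    f, fd = str(f), str(fd)
    if len(f) != len(fd):
        raise ValueError(f"characters have different lengths ({len(f)} vs {len(fd)})")
    elems = tuple(g.transformer(x, y) for x, y in zip(f, fd))
    return PositionwiseOperation(elems, g)


def apply_to_constant(op: PositionwiseOperation, c1: str) -> str:
    """σ̂ applied to the constant character c1...c1."""
    return op.apply(c1 * len(op))


@dataclass
class FitchResult:
    """Root-constrained small-parsimony result.

    ``score`` is the minimal number of state-changing edges over all
    extensions with the root fixed to the requested state; ``state_sets``
    are the bottom-up Fitch sets per vertex, and ``extension`` one
    most-parsimonious extension (ties broken by alphabet order).
    """

    score: int
    state_sets: dict
    extension: dict


def fitch_rooted(t: RootedTree, h, root_state: str, g: GroupAction | None = None,
                 alphabet=None) -> FitchResult:
    """Fitch small parsimony with the root state fixed.

    The usual bottom-up pass (intersect children's sets when possible,
    otherwise unite and count one change) runs up to the root's single
    child; one further change is added iff the fixed root state is absent
    from that vertex's final set.  This +1 correction at the degree-1 root
    is equivalent to rerunning Fitch with a pseudo-leaf pinned to
    ``root_state`` on the stem.
    """
    if alphabet is None and g is not None:
        alphabet = g.alphabet
    hs = as_state_string(h, t)
    if alphabet is not None:
        for c in hs + root_state:
            alphabet.index(c)  # raises on foreign letters
        order = {c: i for i, c in enumerate(alphabet.letters)}
    else:
        order = {c: i for i, c in enumerate(dict.fromkeys(sorted(set(hs) | {root_state})))}
    by_taxon = dict(zip(t.taxon_order, hs))

    state_sets: dict[str, frozenset] = {}
    score = 0

    def up(v: str) -> frozenset:
        nonlocal score
        kids = t.children.get(v, ())
        if not kids:
            s = frozenset({by_taxon[v]})
        else:
            left, right = (up(k) for k in kids)
            inter = left & right
            if inter:
                s = inter
            else:
                s = left | right
                score += 1
        state_sets[v] = s
        return s

    top = t.children[t.root][0]
    top_set = up(top)
    if root_state not in top_set:
        score += 1
    state_sets[t.root] = frozenset({root_state})

    extension: dict[str, str] = {t.root: root_state}

    def down(v: str, parent_state: str) -> None:
        s = state_sets[v]
        if parent_state in s:
            chosen = parent_state
        else:
            chosen = min(s, key=lambda c: order.get(c, len(order)))
        extension[v] = chosen
        for k in t.children.get(v, ()):
            down(k, chosen)

    down(top, root_state)
    return FitchResult(score, state_sets, extension)


def min_substitutions(t: RootedTree, g: GroupAction, f, fd, c1: str | None = None) -> int:
    """Minimal number of single-edge substitutions transforming f into f^d on T.

    The choice of the constant-character state ``c1`` (default: the first
    alphabet letter) does not affect the result.
    """
    fs, fds = as_state_string(f, t), as_state_string(fd, t)
    if c1 is None:
        c1 = g.alphabet.letters[0]
    op = positionwise_sigma(g, fs, fds)
    h = apply_to_constant(op, c1)
    return fitch_rooted(t, h, c1, g=g).score


def exhaustive_oracle(t: RootedTree, g: GroupAction, f, fd,
                      depth_cap: int | None = None, guard: int = 65536) -> int:
    """Breadth-first search over compositions of single-edge substitutions.

    Independent of the Fitch-based computation: characters are letter
    tuples and each generator is applied positionwise over the descendant
    taxa of its edge.  Returns the minimal composition length reaching
    f^d from f.
    """
    a = g.alphabet
    size = a.size ** t.n_leaves
    if size > guard:
        raise ValueError(f"character space of size {size} exceeds the guard ({guard})")
    fs, fds = as_state_string(f, t), as_state_string(fd, t)
    if depth_cap is None:
        depth_cap = size
    gens = []
    for e in t.edges:
        positions = [t.taxon_index(x) for x in t.descendants(e)]
        for s in g.elements[1:]:
            gens.append((positions, s))
    start, goal = tuple(fs), tuple(fds)
    if start == goal:
        return 0
    seen = {start}
    queue = deque([(start, 0)])
    while queue:
        cur, d = queue.popleft()
        if d >= depth_cap:
            break
        for positions, s in gens:
            nxt = list(cur)
            for j in positions:
                nxt[j] = s.apply_letter(a, nxt[j])
            nxt = tuple(nxt)
            if nxt == goal:
                return d + 1
            if nxt not in seen:
                seen.add(nxt)
                queue.append((nxt, d + 1))
    raise RuntimeError(f"target not reached within depth cap {depth_cap}")
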