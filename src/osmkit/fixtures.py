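"""Reproducible synthetic instances: random trees, weights and character pairs.

Everything here is generated from a seed — no external data is ever
needed.  Two named presets reproduce the worked nucleotide instances
used throughout the documentation: ``"fig1"`` is the rooted two-taxon
cherry, ``"fig2"`` the five-taxon tree ((1,2),(3,(4,5))) with the
character pair GTAGA → ACCTC.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .groups import GroupAction, parse_group_spec
from .osm import INDEX_GUARD, build_osm, cayley_shortest_path, min_power_positive
from .phylo import EdgeWeights, RootedTree, normalize_weights, parse_newick
from .transform import exhaustive_oracle, min_substitutions

__all__ = [
    "FixtureSpec",
    "Fixture",
    "make_fixture",
    "random_rooted_tree",
    "random_character",
    "run_equivalence_suite",
]

FIG1_NEWICK = "((1,2));"
FIG2_NEWICK = "((1,2),(3,(4,5)));"


@dataclass
class FixtureSpec:
    """Recipe for one synthetic instance; identical spec + seed → identical output."""

    n_taxa: int = 5
    group: str = "K3ST"
    seed: int = 0
    tree: str = "random"          # "random" | "fig1" | "fig2" | a newick string
    weight_scheme: str = "uniform"  # "uniform" | "exponential"
    guard: int = INDEX_GUARD


@dataclass
class Fixture:
    tree: RootedTree
    weights: EdgeWeights
    group: GroupAction
    f: str
    fd: str
    spec: FixtureSpec = field(repr=False, default=None)


class _TreeNode:
    __slots__ = ("label", "children")

    def __init__(self, label=None, children=None):
        self.label = label
        self.children = children  # [left, right] or None for a leaf

    def newick(self) -> str:
        if self.children is None:
            return self.label
        return "(" + ",".join(c.newick() for c in self.children) + ")"


def random_rooted_tree(n: int, rng: np.random.Generator,
                       taxa: list | None = None) -> RootedTree:
    """Random rooted binary tree by sequential leaf attachment.

    Starting from a single leaf below the root, each further taxon splits
    a uniformly chosen existing edge (the stem included, which pushes the
    previous subtree down one level).
    """
    if n < 1:
        raise ValueError("need at least one taxon")
    if taxa is None:
        taxa = [str(i + 1) for i in range(n)]
    top = _TreeNode(taxa[0])
    for label in taxa[1:]:
        # collect attachable edges: (parent, index) plus the stem (None)
        slots: list = [None]
        stack = [top]
        while stack:
            v = stack.pop()
            if v.children is not None:
                for i, c in enumerate(v.children):
                    slots.append((v, i))
                    stack.append(c)
        choice = slots[int(rng.integers(len(slots)))]
        leaf = _TreeNode(label)
        if choice is None:
            top = _TreeNode(children=[top, leaf])
        else:
            parent, i = choice
            parent.children[i] = _TreeNode(children=[parent.children[i], leaf])
    return parse_newick(f"({top.newick()});")


def random_character(n: int, alphabet, rng: np.random.Generator) -> str:
    return "".join(alphabet.letters[int(i)] for i in rng.integers(alphabet.size, size=n))


def make_fixture(spec: FixtureSpec) -> Fixture:
    """Build the tree, normalized weights and a character pair for a spec."""
    rng = np.random.default_rng(spec.seed)
    group = parse_group_spec(spec.group)
    r = group.alphabet.size

    if spec.tree == "fig1":
        tree = parse_newick(FIG1_NEWICK)
    elif spec.tree == "fig2":
        tree = parse_newick(FIG2_NEWICK)
    elif spec.tree == "random":
        tree = random_rooted_tree(spec.n_taxa, rng)
    else:
        tree = parse_newick(spec.tree)

    if spec.weight_scheme == "uniform":
        weights = normalize_weights(tree, r - 1, uniform=True)
    elif spec.weight_scheme == "exponential":
        lengths = {e: float(rng.exponential(1.0)) for e in tree.edges}
        weights = normalize_weights(tree, r - 1, lengths=lengths)
    else:
        raise ValueError(f"unknown weight scheme {spec.weight_scheme!r}")

    if spec.tree == "fig2" and r == 4:
        f, fd = "GTAGA", "ACCTC"
    else:
        n = tree.n_leaves
        f = random_character(n, group.alphabet, rng)
        fd = random_character(n, group.alphabet, rng)
    return Fixture(tree, weights, group, f, fd, spec)


def run_equivalence_suite(spec: FixtureSpec, methods=("fitch", "bfs", "power"),
                          pairs="all", max_pairs_exhaustive: int = 4096) -> dict:
    """Cross-validate the minimal-substitution computations on one fixture.

    Runs the Fitch-based algorithm and, as requested, the Cayley-graph BFS
    and the minimal-positive-power of the OSM matrix, over all character
    pairs (``pairs="all"``) or a seeded sample (``pairs=<int>``), and
    reports any disagreement.  The power method needs strictly positive
    weights and is skipped (and recorded as skipped) otherwise.
    """
    fx = make_fixture(spec)
    tree, group = fx.tree, fx.group
    a = group.alphabet
    n, r = tree.n_leaves, a.size
    size = r ** n
    if size > spec.guard:
        raise ValueError(f"character space of size {size} exceeds the guard ({spec.guard})")

    rng = np.random.default_rng(spec.seed + 1)
    if pairs == "all":
        if size * size > max_pairs_exhaustive * max_pairs_exhaustive:
            raise ValueError("too many pairs for exhaustive mode; pass a sample size")
        from .osm import index_to_char

        pair_list = [(index_to_char(i, n, a), index_to_char(j, n, a))
                     for i in range(size) for j in range(size)]
    else:
        pair_list = [(random_character(n, a, rng), random_character(n, a, rng))
                     for _ in range(int(pairs))]

    use_power = "power" in methods and fx.weights.all_positive
    osm = build_osm(tree, group, fx.weights, guard=spec.guard) if use_power else None

    disagreements = []
    for f, fd in pair_list:
        results = {"fitch": min_substitutions(tree, group, f, fd)}
        if "bfs" in methods:
            results["bfs"] = cayley_shortest_path(tree, group, f, fd, guard=spec.guard)[0]
        if use_power:
            results["power"] = min_power_positive(osm, f, fd)
        if "oracle" in methods:
            results["oracle"] = exhaustive_oracle(tree, group, f, fd, guard=spec.guard)
        if len(set(results.values())) > 1:
            disagreements.append({"f": f, "fd": fd, **results})
    return {
        "group": group.name,
        "tree": tree.to_newick(include_lengths=False),
        "n_taxa": n,
        "alphabet": "".join(a.letters),
        "pairs": len(pair_list),
        "methods": [m for m in methods if m != "power" or use_power],
        "power_skipped": "power" in methods and not use_power,
        "disagreements": disagreements,
        "ok": not disagreements,
    }
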