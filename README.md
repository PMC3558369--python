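# osmkit

One-step-mutation (OSM) matrices on phylogenetic trees: Abelian permutation
groups acting on character-state alphabets, their Kronecker lift to whole
alignment columns, and an exact, linear-time computation of the minimal
number of substitutions needed to transform one alignment column into
another.

## The problem

An alignment column (a *character*) assigns one state `f : X → C` to every
taxon of a rooted binary tree `T`. Modelling a substitution as a permutation
`σ` of the `r` states, a set `Σ` of substitution types is usable for the OSM
construction exactly when `Σ` is an Abelian group acting *regularly* on `C`:
for every ordered pair of states there is exactly one `σ ∈ Σ` moving the
first onto the second (conditions C1–C6; associativity C7 is automatic for
permutations). For DNA there are precisely two such groups: the Klein
four-group `Z2×Z2 = {s0, s1, s2, s3}` underlying the Kimura
three-substitution-type (K3ST) model, and the cyclic group `Z4`.

A type `σ_i` acting on edge `e` of the tree affects every taxon below `e`
simultaneously; on character space it is the Kronecker lift

```
σ^{e,i} = ∏_{j ∈ de(e)} σ^{j,i},    σ^{j,i} = σ0 ⊗ … ⊗ σ_i ⊗ … ⊗ σ0   (σ_i in position j),
```

a permutation of the `r^n` characters. The set `Σ^T` of all
`|E(T)|·(r−1)` such operators generates the full elementwise group `Σ^n`,
and the OSM matrix is their convex combination

```
M_T = Σ_{e ∈ E(T)} Σ_{i=1}^{r−1} α_{e,i} · p_e · σ^{e,i},
```

with `p_e` the relative branch length and `α_{e,i}` the probability that a
substitution on `e` is of type `i`. `M_T` is doubly stochastic (Birkhoff)
and describes one random substitution somewhere on the tree.

The central computation: given columns `f` and `f^d`, the minimal number
`m` of single-edge substitutions with `σ^{e_1,i_1} ⋯ σ^{e_m,i_m}(f) = f^d`.
Regularity yields the unique positionwise operation `σ̂` with `σ̂(f) = f^d`;
applying `σ̂` to a constant column `c1…c1` gives a column `h`; and `m` is
the Fitch small-parsimony score of `h` with the root state pinned to `c1`.
This equals the shortest-path distance between `f` and `f^d` in the Cayley
graph of `Σ^T` and the smallest `k` with `(M_T^k)[f, f^d] > 0` — both of
which osmkit also computes, as independent cross-checks.

Beyond DNA, any alphabet size works: `osmkit` enumerates the admissible
constructions (e.g. the four twenty-state products `Z20`, `Z2×Z10`,
`Z4×Z5`, `Z2×Z2×Z5` and their coset binnings of the amino acids), and
audits arbitrary substitution models via Birkhoff decomposition — the
symmetric GTR matrix decomposes into the six pair transpositions but
violates closure (C3), commutativity (C4) and fixed-point-freeness (C5),
while models with non-uniform stationary distributions are not even
decomposable.

## Worked example

The five-taxon tree `((1,2),(3,(4,5)))` and the column pair
`GTAGA → ACCTC`:

```
$ echo '((1,2),(3,(4,5)));' > fig2.nwk
$ osmkit mindist --tree fig2.nwk --group K3ST --from GTAGA --to ACCTC --oracle
operation: (s1,s1,s2,s2,s2)
h = GGCCC (root state A)
m = 2
oracle = 2
$ osmkit mindist --tree fig2.nwk --group Z4 --from GTAGA --to ACCTC
operation: (s'3,s'1,s'3,s'1,s'3)
h = CGCGC (root state A)
m = 3
```

Under K3ST the transformation needs a transition `s1` at taxa 1–2 and the
transversion `s2` at taxa 3–5; both blocks can be "pulled up" onto internal
edges, so two substitutions suffice (`m = 2`). Under the cyclic group the
required types alternate along the tree and three substitutions are needed —
the minimal count depends on the group, not just on the characters. The
`--oracle` flag re-derives `m` by breadth-first search over generator
compositions and exits non-zero on disagreement.

The same from Python:

```python
from osmkit import k3st, parse_newick, min_substitutions, build_osm, normalize_weights

tree = parse_newick("((1,2),(3,(4,5)));")
g = k3st()
min_substitutions(tree, g, "GTAGA", "ACCTC")   # -> 2

m = build_osm(tree, g, normalize_weights(tree, g.size - 1, uniform=True))
m.is_doubly_stochastic()                        # -> True
```

Other entry points: `osmkit group check|show`, `osmkit tree info`,
`osmkit osm build` (MatrixMarket + decomposition TSV export),
`osmkit cayley path`, `osmkit audit model`, `osmkit fixtures make`,
`osmkit verify equivalence`.

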