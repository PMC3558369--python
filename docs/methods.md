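# Methods

## Model

osmkit models a substitution as a permutation of the character-state
alphabet and a *substitution regime* as a set `Σ` of such permutations
that, together with the identity, forms an Abelian group acting regularly
on the states. The seven conditions checked by `groups.check_conditions`
are: C1 bijectivity, C2 regularity (exactly one element per ordered state
pair — hence `|Σ| = r`), C3 closure, C4 commutativity, C5 identity present
and every other element fixed-point free, C6 inverses present, C7
associativity (automatic for permutations; reported for completeness).
Regularity is what makes the per-position transformation between two
columns *unique*, and commutativity is what lets substitutions be
reordered along root-to-leaf paths; both are load-bearing in the proof
sketched below.

Trees are rooted, binary, with a degree-1 root ρ: the stem edge above the
first split is a genuine edge on which a substitution can act (it affects
all taxa at once). A type lifted to edge `e` acts simultaneously on all
taxa below `e`; algebraically the lift is a Kronecker product with the
type in the descendant positions and the identity elsewhere, and the
internal-edge operator factors exactly into the product of its
descendants' pendant lifts. The OSM matrix is the convex combination of
all lifted operators, weighted by relative branch length `p_e` times
per-edge type probability `α_{e,i}`; double stochasticity is immediate
from Birkhoff's theorem.

## The minimal-substitution computation

`transform.min_substitutions` computes, in three steps, the minimal
number of single-edge substitutions turning column `f` into `f^d`:

1. **Positionwise operation.** By regularity there is exactly one
   `σ̂_j ∈ Σ` with `σ̂_j(f_j) = f^d_j` per position.
2. **Transport to a constant column.** `h := σ̂(c1…c1)`. By commutativity,
   an edge assignment transforms `f` into `f^d` iff it evolves the
   constant column into `h`; two positions of `h` agree iff the
   corresponding `σ̂_j` agree, so parsimony on `h` stands in for parsimony
   on the operation itself.
3. **Root-constrained Fitch.** The minimal number of state-changing edges
   over all extensions of `h` with the root pinned to `c1` is the answer.

The Fitch pass runs bottom-up to the root's single child (intersect child
sets when possible, otherwise unite and count one change) and adds 1 iff
`c1` is absent from the final set. This "+1 at the degree-1 root" is
equivalent to running Fitch with a pseudo-leaf pinned to `c1` on the stem,
and is verified in the tests against a brute-force minimum over all
root-constrained extensions. The returned extension is one
most-parsimonious witness, ties broken by alphabet order; only the score
is contractual. The choice of `c1` provably does not affect the score
(tested over all four nucleotide choices).

Two independent routes cross-check the score wherever the character space
is small enough to enumerate: breadth-first search in the Cayley graph of
`Σ^T` (implemented twice — once on integer character indices with
vectorized generator maps, once on letter tuples in the test oracle), and
the smallest `k` for which `(M_T^k)[f, f^d] > 0`. The equivalence is
asserted exhaustively for all character pairs at n = 2 (256 pairs) and
n = 3 (4096 pairs, all three labelled tree shapes) under both nucleotide
groups, and on 100 random pairs per group at n = 4 and n = 5. The power
route requires strictly positive weights — with zeros the support of
`M_T^k` and Cayley reachability differ — so `min_power_positive` refuses
zero-weight decompositions rather than silently disagreeing with BFS.

## Conventions and numerical choices

- **Alphabet order** is explicit and user-visible; the DNA preset is
  A, C, G, T and all reference matrices are asserted under it. Twenty
  states default to the amino acids in one-letter alphabetical order.
- **Matrix convention**: `M[i, j] = 1` iff `σ(i) = j` (sources on rows),
  the convention in which the standard printed forms of the K3ST and sGTR
  matrices come out. Under it `matrix(a∘b) = matrix(b)·matrix(a)`; inside
  an Abelian group both orders coincide, which is why concatenation and
  matrix product are interchangeable there. The property tests assert the
  order-correct identity for arbitrary permutations.
- **Kronecker/index convention**: left factor most significant; character
  index `Σ_j index(f_j)·r^(n−1−j)` with taxon 1 leftmost. This makes the
  elementwise action literally equal to `σ_1 ⊗ … ⊗ σ_n`.
- **K3ST labels**: `s1 = τ1⊗τ0` (transitions A↔G, C↔T), `s2 = τ0⊗τ1`
  (A↔C, G↔T), `s3 = τ1⊗τ1` (A↔T, C↔G). The bare `Z4` preset is generated
  by A→G→T→C→A; `K2ST` exposes the A→C→G→T→A variant, under which the
  squared element is the transition.
- **Newick policy**: a bifurcating newick root gets a stem edge and a
  degree-1 root prepended (`add_stem`, default); the stem's length
  defaults to absent, which normalizes to `p = 0` unless uniform weights
  are requested. Taxon order is the left-to-right leaf order of the
  newick string unless overridden, and is logged by the CLI. Edge ids are
  child-vertex names (`e_1`, `e_12`, …).
- **Weights**: `p_e` normalized to sum to 1; `α_{e,i}` defaults to the
  uniform `1/(r−1)` — nothing in the framework prescribes how to estimate
  them from data, so they are user-overridable per edge. Note that with
  uniform `α` the OSM matrix is symmetric even for non-involution groups
  (each element is paired with its equally-weighted inverse); asymmetry
  for `Z4` appears only under unequal type weights, and the tests assert
  exactly that.
- **Guards**: dense/enumerative operations are capped at `r^n ≤ 65536`
  (index maps, BFS) and `r^n ≤ 4096` (dense matrices, explicit Cayley
  graphs); the Fitch-based score itself is linear in `n` and uncapped.
- **Birkhoff decomposition** (`modelcompat`): greedy extraction where each
  step takes a perfect matching on the positive support maximizing the
  minimum covered entry (binary search over thresholds, matchings via
  scipy's Hopcroft–Karp), subtracts the bottleneck weight, and repeats; at
  most `(r−1)² + 1` terms for exact inputs. Decompositions are not unique
  — only the reconstruction is contractual, and the support-recovery test
  (decomposing a convex sum of group elements yields only group elements)
  holds because extraction never leaves the positive support. Stochasticity
  tolerance defaults to 1e−9 (model matrices are often estimated in
  floating point); reconstruction is tested to 1e−10, exact convex-sum
  identities to 1e−12.
- **Construction-level counting**: `enumerate_constructions(r)` lists
  unordered factorizations into factors ≥ 2, so twenty states yield four
  constructions (`Z20`, `Z2×Z10`, `Z4×Z5`, `Z2×Z2×Z5`) even though only
  two abstract isomorphism classes exist (`Z20 ≅ Z4×Z5`,
  `Z2×Z10 ≅ Z2×Z2×Z5`; the element-order multiset is a complete invariant
  for finite Abelian groups and backs `reduce_by_isomorphism`, which is
  provided but never applied implicitly). The constructions differ as
  *permutation* groups on the alphabet, which is what matters for coset
  binnings.

## Synthetic data

`fixtures.make_fixture` generates rooted binary trees by sequential leaf
attachment (each new taxon splits a uniformly chosen edge, stem included),
uniform random character pairs, and either uniform or normalized
exponential branch weights, all from a single integer seed; identical
spec + seed reproduce byte-identical fixtures. Two presets pin the worked
instances used in the documentation: the two-taxon cherry and the
five-taxon tree `((1,2),(3,(4,5)))` with the pair GTAGA → ACCTC. The
five-taxon topology is fixed by convention; the printed scores (2 under
K3ST, 3 under Z4) are insensitive to which caterpillar resolution of the
figure is chosen.

The generator emulates tree shape and column content only: states are
i.i.d. uniform, with no substitution process run along the tree, no rate
heterogeneity, no indels or missing data. Passing tests therefore
establish the combinatorial and algebraic guarantees (scores, distances,
stochasticity, group conditions) on arbitrary inputs — they do not say
anything about statistical behaviour on empirically evolved alignments.

## Limitations

- Non-Abelian regimes are out of scope by design; the framework's
  conditions exclude them (that is the point of the sGTR audit).
- Only the minimal substitution *count* is computed, not a posterior
  distribution over substitution numbers or placements, and not the set
  of all optimal placements.
- Rate-matrix (continuous-time) models are audited only through their
  transition matrices; no exponentiation or parameter fitting is done.
- The amino-acid coset binnings are purely group-theoretic; none of the
  four twenty-state constructions matches biochemical binnings such as
  hydrophobicity classes, and osmkit makes no attempt to search for a
  biologically optimal one.
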