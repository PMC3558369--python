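"""Permutation groups acting on character-state alphabets.

A substitution type is modelled as a permutation of the character states.
A set of such permutations is usable for one-step-mutation (OSM)
constructions precisely when, together with the identity, it forms an
Abelian group acting *regularly* on the alphabet: for every ordered pair
of states exactly one element maps the first onto the second.  The
canonical nucleotide example is the Klein four-group behind the Kimura
three-substitution-type (K3ST) model; the cyclic group of order four is
the only other choice for four states.

Matrix convention
-----------------
Permutation matrices follow the convention used throughout the
substitution-model literature: ``M[i, j] = 1`` iff the permutation sends
state ``i`` to state ``j`` (sources on rows, targets on columns).  Under
this convention ``matrix(a ∘ b) = matrix(b) @ matrix(a)``; for the
commuting elements of an Abelian group both orders coincide, so the
familiar identification of concatenation with matrix multiplication is
exact inside a group.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Alphabet",
    "Permutation",
    "GroupAction",
    "ConditionReport",
    "DNA",
    "BINARY",
    "AA20",
    "compose",
    "kronecker",
    "build_cyclic",
    "build_product",
    "build_from_construction",
    "check_conditions",
    "transformer",
    "enumerate_four_cycle_groups",
    "enumerate_constructions",
    "coset_partition",
    "isomorphism_key",
    "reduce_by_isomorphism",
    "k3st",
    "z2",
    "z4_dna",
    "parse_group_spec",
    "permutation_to_tsv",
]


class Alphabet:
    """An ordered set of distinct character states.

    The ordering is significant: it fixes row/column order of permutation
    matrices and the mixed-radix indexing of whole characters.  The DNA
    preset orders states ``A, C, G, T``.
    """

    __slots__ = ("letters", "_index")

    def __init__(self, letters: Iterable[str]):
        letters = tuple(str(c) for c in letters)
        if len(set(letters)) != len(letters):
            raise ValueError(f"alphabet letters must be unique, got {letters!r}")
        if not letters:
            raise ValueError("alphabet must contain at least one letter")
        object.__setattr__(self, "letters", letters)
        object.__setattr__(self, "_index", {c: i for i, c in enumerate(letters)})

    def __setattr__(self, name, value):  # immutable
        raise AttributeError("Alphabet is immutable")

    @property
    def size(self) -> int:
        return len(self.letters)

    def index(self, letter: str) -> int:
        try:
            return self._index[letter]
        except KeyError:
            raise KeyError(f"letter {letter!r} not in alphabet {''.join(self.letters)}") from None

    def __len__(self) -> int:
        return len(self.letters)

    def __iter__(self):
        return iter(self.letters)

    def __contains__(self, letter) -> bool:
        return letter in self._index

    def __eq__(self, other) -> bool:
        return isinstance(other, Alphabet) and self.letters == other.letters

    def __hash__(self) -> int:
        return hash(self.letters)

    def __repr__(self) -> str:
        return f"Alphabet({''.join(self.letters)!r})"


DNA = Alphabet("ACGT")
BINARY = Alphabet("01")
#: The twenty amino acids in their conventional one-letter alphabetical order.
AA20 = Alphabet("ACDEFGHIKLMNPQRSTVWY")

_PRESET_ALPHABETS = {2: BINARY, 4: DNA, 20: AA20}


def default_alphabet(r: int) -> Alphabet:
    """A conventional alphabet for ``r`` states (DNA for 4, amino acids for 20)."""
    if r in _PRESET_ALPHABETS:
        return _PRESET_ALPHABETS[r]
    if r <= 36:
        digits = "0123456789abcdefghijklmnopqrstuvwxyz"
        return Alphabet(digits[:r])
    return Alphabet(f"c{i}" for i in range(r))


@dataclass(frozen=True)
class Permutation:
    """A bijection on alphabet indices, usable as a function or a 0/1 matrix.

    ``mapping[i]`` is the index the permutation sends ``i`` to.
    """

    mapping: tuple
    label: str = ""

    def __post_init__(self):
        m = tuple(int(x) for x in self.mapping)
        if sorted(m) != list(range(len(m))):
            raise ValueError(f"mapping {m!r} is not a bijection on 0..{len(m) - 1}")
        object.__setattr__(self, "mapping", m)

    @classmethod
    def identity(cls, r: int, label: str = "s0") -> "Permutation":
        return cls(tuple(range(r)), label)

    @classmethod
    def from_cycle_letters(cls, alphabet: Alphabet, cycle: Sequence[str], label: str = "") -> "Permutation":
        """Build the single-cycle permutation c0 -> c1 -> ... -> c0."""
        idx = [alphabet.index(c) for c in cycle]
        if len(set(idx)) != len(idx):
            raise ValueError(f"cycle {cycle!r} repeats a letter")
        m = list(range(alphabet.size))
        for a, b in zip(idx, idx[1:] + idx[:1]):
            m[a] = b
        return cls(tuple(m), label)

    @classmethod
    def from_cycles(cls, alphabet: Alphabet, text: str, label: str = "") -> "Permutation":
        """Parse disjoint cycle notation, e.g. ``"(A G)(C T)"``; ``"e"`` is the identity."""
        m = list(range(alphabet.size))
        text = text.strip()
        if text in ("e", "id", "()", ""):
            return cls(tuple(m), label)
        if text.count("(") != text.count(")") or not text.startswith("("):
            raise ValueError(f"malformed cycle notation: {text!r}")
        for chunk in text.replace(")", ")|").split("|"):
            chunk = chunk.strip()
            if not chunk:
                continue
            letters = chunk.strip("()").replace(",", " ").split()
            idx = [alphabet.index(c) for c in letters]
            for a, b in zip(idx, idx[1:] + idx[:1]):
                if m[a] != a:
                    raise ValueError(f"cycles are not disjoint in {text!r}")
                m[a] = b
        return cls(tuple(m), label)

    @property
    def size(self) -> int:
        return len(self.mapping)

    def __call__(self, i: int) -> int:
        return self.mapping[i]

    def apply_letter(self, alphabet: Alphabet, letter: str) -> str:
        return alphabet.letters[self.mapping[alphabet.index(letter)]]

    @property
    def matrix(self) -> np.ndarray:
        """Dense 0/1 matrix with ``M[i, mapping[i]] = 1`` (sources on rows)."""
        r = self.size
        m = np.zeros((r, r), dtype=int)
        m[np.arange(r), self.mapping] = 1
        return m

    def inverse(self, label: str | None = None) -> "Permutation":
        inv = [0] * self.size
        for i, j in enumerate(self.mapping):
            inv[j] = i
        return Permutation(tuple(inv), label if label is not None else f"{self.label}^-1")

    @property
    def is_identity(self) -> bool:
        return all(i == j for i, j in enumerate(self.mapping))

    def fixed_points(self) -> tuple:
        return tuple(i for i, j in enumerate(self.mapping) if i == j)

    def order(self) -> int:
        k, p = 1, self
        while not p.is_identity:
            p = compose(p, self)
            k += 1
        return k

    def relabel(self, label: str) -> "Permutation":
        return Permutation(self.mapping, label)

    def __eq__(self, other) -> bool:
        return isinstance(other, Permutation) and self.mapping == other.mapping

    def __hash__(self) -> int:
        return hash(self.mapping)

    def __repr__(self) -> str:
        return f"Permutation({self.mapping!r}, label={self.label!r})"


def compose(a: Permutation, b: Permutation, label: str | None = None) -> Permutation:
    """The permutation ``x -> a(b(x))`` (apply ``b`` first, then ``a``)."""
    if a.size != b.size:
        raise ValueError(f"size mismatch: {a.size} vs {b.size}")
    m = tuple(a.mapping[x] for x in b.mapping)
    return Permutation(m, label if label is not None else f"{a.label}∘{b.label}")


def kronecker(a: Permutation, b: Permutation, label: str | None = None) -> Permutation:
    """Kronecker product of two permutations, left factor most significant.

    The combined index is ``i_a * r_b + i_b``, and the matrix of the result
    is the Kronecker product of the factor matrices.
    """
    rb = b.size
    m = tuple(a.mapping[ia] * rb + b.mapping[ib] for ia in range(a.size) for ib in range(rb))
    return Permutation(m, label if label is not None else f"{a.label}⊗{b.label}")


@dataclass
class ConditionCheck:
    passed: bool
    witness: str | None = None


class ConditionReport:
    """Per-condition audit of a candidate permutation set.

    The seven conditions characterise an Abelian group acting regularly on
    the alphabet: C1 bijectivity, C2 regularity (exactly one element per
    ordered state pair), C3 closure, C4 commutativity, C5 identity present
    and all other elements fixed-point free, C6 inverses present, C7
    associativity (automatic for permutations).  A set qualifies iff C1-C6
    all hold.
    """

    CONDITIONS = ("C1", "C2", "C3", "C4", "C5", "C6", "C7")

    def __init__(self, checks: dict):
        self.checks = {c: checks[c] for c in self.CONDITIONS}

    def __getitem__(self, cond: str) -> ConditionCheck:
        return self.checks[cond]

    @property
    def ok(self) -> bool:
        """True iff C1-C6 all pass (C7 holds for any permutation set)."""
        return all(self.checks[c].passed for c in ("C1", "C2", "C3", "C4", "C5", "C6"))

    def failures(self) -> list:
        return [c for c in self.CONDITIONS if not self.checks[c].passed]

    def to_dict(self) -> dict:
        return {
            c: {"passed": chk.passed, "witness": chk.witness}
            for c, chk in self.checks.items()
        }

    def __str__(self) -> str:
        lines = []
        for c, chk in self.checks.items():
            status = "pass" if chk.passed else "FAIL"
            line = f"{c}: {status}"
            if chk.witness:
                line += f"  ({chk.witness})"
            lines.append(line)
        verdict = "admissible (Abelian, regular action)" if self.ok else "NOT admissible"
        lines.append(f"verdict: {verdict}")
        return "\n".join(lines)


def check_conditions(candidate: Iterable[Permutation], alphabet: Alphabet | None = None) -> ConditionReport:
    """Audit a permutation set against the group conditions C1-C7.

    All failures are reported (each with one concrete witness), not just
    the first, so that model audits produce complete diagnostics.
    """
    elems = list(candidate)
    if not elems:
        raise ValueError("empty candidate set")
    r = elems[0].size
    if any(p.size != r for p in elems):
        raise ValueError("candidate permutations act on different alphabet sizes")
    letters = alphabet.letters if alphabet is not None else tuple(str(i) for i in range(r))
    if alphabet is not None and alphabet.size != r:
        raise ValueError("alphabet size does not match permutations")

    def name(p: Permutation) -> str:
        return p.label or str(p.mapping)

    checks: dict[str, ConditionCheck] = {}
    # C1: bijectivity -- enforced by the Permutation type; re-verified here.
    checks["C1"] = ConditionCheck(True)

    # C2: regular action -- exactly one element per ordered letter pair.
    c2 = ConditionCheck(True)
    for i in range(r):
        for j in range(r):
            movers = [p for p in elems if p.mapping[i] == j]
            if len(movers) != 1:
                c2 = ConditionCheck(
                    False,
                    f"{len(movers)} elements map {letters[i]} to {letters[j]} "
                    f"({', '.join(name(p) for p in movers) or 'none'})",
                )
                break
        if not c2.passed:
            break
    checks["C2"] = c2

    elem_set = set(elems)
    # C3: closure under composition (witness in matrix-product order: x·y = apply x then y).
    c3 = ConditionCheck(True)
    for a, b in itertools.product(elems, repeat=2):
        if compose(b, a) not in elem_set:
            c3 = ConditionCheck(False, f"{name(a)}·{name(b)} is not in the set")
            break
    checks["C3"] = c3

    # C4: commutativity.
    c4 = ConditionCheck(True)
    for a, b in itertools.combinations(elems, 2):
        if compose(a, b) != compose(b, a):
            c4 = ConditionCheck(False, f"{name(a)}·{name(b)} ≠ {name(b)}·{name(a)}")
            break
    checks["C4"] = c4

    # C5: identity present; every other element fixed-point free.
    ident = Permutation.identity(r)
    if ident not in elem_set:
        checks["C5"] = ConditionCheck(False, "identity permutation missing")
    else:
        c5 = ConditionCheck(True)
        for p in elems:
            if p.is_identity:
                continue
            fp = p.fixed_points()
            if fp:
                c5 = ConditionCheck(False, f"{name(p)} fixes {letters[fp[0]]} (diagonal entry)")
                break
        checks["C5"] = c5

    # C6: inverses present.
    c6 = ConditionCheck(True)
    for p in elems:
        if p.inverse() not in elem_set:
            c6 = ConditionCheck(False, f"inverse of {name(p)} is not in the set")
            break
    checks["C6"] = c6

    # C7: associativity holds for any set of permutations.
    checks["C7"] = ConditionCheck(True)
    return ConditionReport(checks)


class GroupAction:
    """A finite Abelian group of permutations acting regularly on an alphabet.

    Elements are stored identity-first.  Construction validates conditions
    C1-C6 (pass ``validate=False`` only for sets already known to qualify).
    """

    def __init__(self, alphabet: Alphabet, elements: Sequence[Permutation],
                 name: str = "", validate: bool = True):
        elements = list(elements)
        if not elements or not elements[0].is_identity:
            # normalise: put the identity first if present
            idx = next((k for k, p in enumerate(elements) if p.is_identity), None)
            if idx is None:
                raise ValueError("group must contain the identity permutation")
            elements.insert(0, elements.pop(idx))
        if validate:
            report = check_conditions(elements, alphabet)
            if not report.ok:
                raise ValueError(f"not an admissible group action:\n{report}")
        self.alphabet = alphabet
        self.elements = tuple(elements)
        self.name = name or "group"
        self._by_mapping = {p.mapping: k for k, p in enumerate(self.elements)}
        self._by_label = {p.label: k for k, p in enumerate(self.elements)}
        r = alphabet.size
        # transformer table: _move[i, j] = index of the unique element sending i to j
        move = np.empty((r, r), dtype=np.int64)
        for k, p in enumerate(self.elements):
            for i, j in enumerate(p.mapping):
                move[i, j] = k
        self._move = move
        n = len(self.elements)
        table = np.empty((n, n), dtype=np.int64)
        for i, a in enumerate(self.elements):
            for j, b in enumerate(self.elements):
                table[i, j] = self._by_mapping[compose(a, b).mapping]
        self.composition_table = table

    @property
    def size(self) -> int:
        return len(self.elements)

    @property
    def identity(self) -> Permutation:
        return self.elements[0]

    def __len__(self) -> int:
        return len(self.elements)

    def __iter__(self):
        return iter(self.elements)

    def __getitem__(self, k: int) -> Permutation:
        return self.elements[k]

    def __contains__(self, p: Permutation) -> bool:
        return p.mapping in self._by_mapping

    def element(self, label: str) -> Permutation:
        return self.elements[self._by_label[label]]

    def index_of(self, p: Permutation) -> int:
        return self._by_mapping[p.mapping]

    def inverse_index(self, k: int) -> int:
        return self._by_mapping[self.elements[k].inverse().mapping]

    def transformer(self, from_letter: str, to_letter: str) -> Permutation:
        """The unique element mapping ``from_letter`` to ``to_letter`` (regularity)."""
        i = self.alphabet.index(from_letter)
        j = self.alphabet.index(to_letter)
        return self.elements[int(self._move[i, j])]

    def mapping_set(self) -> frozenset:
        return frozenset(p.mapping for p in self.elements)

    @property
    def is_involution_group(self) -> bool:
        """True iff every element is its own inverse (e.g. powers of Z2)."""
        return all(compose(p, p).is_identity for p in self.elements)

    def condition_report(self) -> ConditionReport:
        return check_conditions(self.elements, self.alphabet)

    def __repr__(self) -> str:
        return (f"GroupAction({self.name!r}, r={self.alphabet.size}, "
                f"elements=[{', '.join(p.label for p in self.elements)}])")


def transformer(g: GroupAction, from_letter: str, to_letter: str) -> Permutation:
    """Module-level alias for :meth:`GroupAction.transformer`."""
    return g.transformer(from_letter, to_letter)


# ---------------------------------------------------------------------------
# constructions


def _cycle_orbit(p: Permutation) -> list:
    orbit, x = [0], p.mapping[0]
    while x != 0:
        orbit.append(x)
        x = p.mapping[x]
    return orbit


def build_cyclic(r: int | None = None, cycle: Permutation | None = None,
                 alphabet: Alphabet | None = None, label_prefix: str = "s",
                 name: str | None = None) -> GroupAction:
    """The cyclic group generated by a single full cycle on the alphabet.

    With no explicit generator the cycle sends letter ``i`` to letter
    ``i + 1 (mod r)``.  The generator must be a single ``r``-cycle;
    otherwise the resulting set of ``r`` powers would not act regularly.
    """
    if alphabet is None:
        if r is None and cycle is None:
            raise ValueError("need r, an alphabet or an explicit generator cycle")
        alphabet = default_alphabet(r if r is not None else cycle.size)
    r = alphabet.size
    if cycle is None:
        cycle = Permutation(tuple((i + 1) % r for i in range(r)))
    if cycle.size != r:
        raise ValueError("generator size does not match alphabet size")
    if len(_cycle_orbit(cycle)) != r:
        raise ValueError("generator is not a single full cycle; the group would not act regularly")
    elems = [Permutation.identity(r, f"{label_prefix}0")]
    p = cycle
    for k in range(1, r):
        elems.append(p.relabel(f"{label_prefix}{k}"))
        p = compose(p, cycle)
    return GroupAction(alphabet, elems, name or f"Z{r}", validate=False)


def build_product(factors: Sequence[GroupAction], alphabet: Alphabet | None = None,
                  name: str | None = None, label_prefix: str = "g") -> GroupAction:
    """Direct product of group actions via Kronecker products of their elements.

    The product acts on an alphabet of size ``prod(r_k)``; combined state
    indices put the first factor in the most significant position.  Element
    order follows ``itertools.product`` (last factor varies fastest), with
    generic labels; presets such as :func:`k3st` fix their own labels.
    """
    factors = list(factors)
    if not factors:
        raise ValueError("empty factor list")
    r = 1
    for f in factors:
        r *= f.alphabet.size
    if alphabet is None:
        alphabet = default_alphabet(r)
    if alphabet.size != r:
        raise ValueError(f"alphabet size {alphabet.size} != product size {r}")
    elems = []
    for k, combo in enumerate(itertools.product(*[f.elements for f in factors])):
        p = combo[0]
        for q in combo[1:]:
            p = kronecker(p, q)
        elems.append(p.relabel(f"{label_prefix}{k}"))
    pname = name or "×".join(f.name for f in factors)
    return GroupAction(alphabet, elems, pname, validate=False)


def build_from_construction(factors: Sequence[int], alphabet: Alphabet | None = None,
                            name: str | None = None) -> GroupAction:
    """Direct product of default cyclic groups with the given orders."""
    parts = [build_cyclic(k) for k in factors]
    if len(parts) == 1:
        g = parts[0]
        if alphabet is not None and alphabet != g.alphabet:
            g = GroupAction(alphabet, g.elements, g.name, validate=False)
        return g
    nm = name or "×".join(f"Z{k}" for k in factors)
    return build_product(parts, alphabet=alphabet, name=nm)


# ---------------------------------------------------------------------------
# presets


def z2() -> GroupAction:
    """The two-element group on a binary alphabet: identity τ0 and flip τ1."""
    t0 = Permutation.identity(2, "t0")
    t1 = Permutation((1, 0), "t1")
    return GroupAction(BINARY, [t0, t1], "Z2", validate=False)


def k3st() -> GroupAction:
    """The Klein four-group behind the K3ST model, over A,C,G,T.

    s1 exchanges purines and pyrimidines internally (A<->G, C<->T:
    transitions); s2 is the A<->C / G<->T transversion pair; s3 the
    A<->T / C<->G transversion pair.  s1 = τ1⊗τ0, s2 = τ0⊗τ1, s3 = τ1⊗τ1.
    """
    t0 = Permutation.identity(2)
    t1 = Permutation((1, 0))
    elems = [
        kronecker(t0, t0, "s0"),
        kronecker(t1, t0, "s1"),
        kronecker(t0, t1, "s2"),
        kronecker(t1, t1, "s3"),
    ]
    return GroupAction(DNA, elems, "K3ST", validate=False)


def z4_dna(convention: str = "default") -> GroupAction:
    """The cyclic group of order four on DNA.

    ``"default"`` generates with the cycle A→G→T→C→A; ``"k2st"`` uses
    A→C→G→T→A, the generator under which the squared element is the
    transition and the odd powers are undistinguished transversions
    (the Kimura two-parameter grouping).
    """
    if convention == "default":
        gen = Permutation.from_cycle_letters(DNA, "AGTC")
        return build_cyclic(cycle=gen, alphabet=DNA, label_prefix="s'", name="Z4")
    if convention in ("k2st", "K2ST"):
        gen = Permutation.from_cycle_letters(DNA, "ACGT")
        return build_cyclic(cycle=gen, alphabet=DNA, label_prefix="s'", name="Z4-K2ST")
    raise ValueError(f"unknown Z4 convention {convention!r}")


# ---------------------------------------------------------------------------
# enumeration


@dataclass
class FourCycleEnumeration:
    count_cycles: int
    distinct_groups: int
    groups: list = field(default_factory=list)
    cycles_per_group: dict = field(default_factory=dict)


def enumerate_four_cycle_groups(alphabet: Alphabet = DNA) -> FourCycleEnumeration:
    """All 4-cycles on a four-letter alphabet and the distinct cyclic groups they generate.

    There are 3! = 6 four-cycles; a cycle and its inverse generate the same
    group, so they collapse to three distinguishable cyclic groups.
    """
    if alphabet.size != 4:
        raise ValueError("four-cycle enumeration needs an alphabet of size 4")
    first, rest = alphabet.letters[0], alphabet.letters[1:]
    seen: dict[frozenset, GroupAction] = {}
    counts: dict[frozenset, int] = {}
    n_cycles = 0
    for perm_rest in itertools.permutations(rest):
        cycle_letters = (first,) + perm_rest
        n_cycles += 1
        gen = Permutation.from_cycle_letters(alphabet, cycle_letters)
        g = build_cyclic(cycle=gen, alphabet=alphabet,
                         name="Z4(" + "→".join(cycle_letters + (first,)) + ")")
        key = g.mapping_set()
        if key not in seen:
            seen[key] = g
        counts[key] = counts.get(key, 0) + 1
    return FourCycleEnumeration(n_cycles, len(seen), list(seen.values()),
                                {seen[k].name: v for k, v in counts.items()})


def enumerate_constructions(r: int) -> list:
    """All unordered factorizations of ``r`` into integer factors ≥ 2.

    Each factorization names a direct product of cyclic groups of those
    orders, i.e. one way of endowing an ``r``-letter alphabet with an
    Abelian group action.  Distinct factorizations are kept distinct even
    when the resulting groups are isomorphic as abstract groups (for
    twenty states this yields the four constructions Z20, Z2×Z10, Z4×Z5
    and Z2×Z2×Z5); see :func:`reduce_by_isomorphism` for the coarser view.
    """
    if r < 2:
        raise ValueError("need r >= 2")

    def rec(m: int, min_f: int):
        if m == 1:
            yield ()
            return
        d = min_f
        while d * d <= m:
            if m % d == 0:
                for rest in rec(m // d, d):
                    yield (d,) + rest
            d += 1
        yield (m,)

    return sorted(rec(r, 2))


def isomorphism_key(g: GroupAction) -> tuple:
    """Multiset of element orders — a complete isomorphism invariant for finite Abelian groups."""
    return tuple(sorted(p.order() for p in g.elements))


def reduce_by_isomorphism(groups: Iterable[GroupAction]) -> list:
    """One representative per abstract isomorphism class (never applied implicitly)."""
    reps: dict[tuple, GroupAction] = {}
    for g in groups:
        reps.setdefault(isomorphism_key(g), g)
    return list(reps.values())


def coset_partition(g: GroupAction, subgroup: GroupAction | Sequence[Permutation]) -> list:
    """Partition the alphabet into orbits of a subgroup of ``g``.

    Because the full group acts regularly the orbits are the cosets of the
    subgroup, so every block has exactly ``|subgroup|`` letters (e.g. the
    Z5 subgroup of Z2×Z2×Z5 bins twenty states into four blocks of five).
    Blocks are ordered by their first letter in alphabet order.
    """
    subs = list(subgroup.elements) if isinstance(subgroup, GroupAction) else list(subgroup)
    for p in subs:
        if p not in g:
            raise ValueError(f"element {p.label or p.mapping} is not in {g.name}")
    letters = g.alphabet.letters
    seen: set[int] = set()
    blocks = []
    for i in range(len(letters)):
        if i in seen:
            continue
        orbit = sorted({p.mapping[i] for p in subs})
        if set(orbit) & seen:
            raise ValueError("subgroup orbits are not disjoint; not closed under composition")
        seen.update(orbit)
        blocks.append(tuple(letters[j] for j in orbit))
    return blocks


# ---------------------------------------------------------------------------
# group spec mini-language


def parse_group_spec(spec: str, alphabet: Alphabet | None = None) -> GroupAction:
    """Parse a group specification string into a :class:`GroupAction`.

    Accepted forms::

        K3ST                    Klein four-group / Kimura 3ST, on A,C,G,T
        K2ST                    cyclic Z4 generated by A→C→G→T→A
        Z4                      cyclic Z4 on DNA, generated by A→G→T→C→A
        Z4:A>G>T>C>A            cyclic group with an explicit generator cycle
        Z2xZ2, Z4xZ5, Z2xZ2xZ5  direct products of cyclic groups
        (A G)(C T),(A C)(G T),...   explicit permutation list in cycle notation
    """
    spec = spec.strip()
    upper = spec.upper()
    if upper == "K3ST":
        return k3st()
    if upper == "K2ST":
        return z4_dna("k2st")
    if "(" in spec:
        if alphabet is None:
            raise ValueError("explicit permutation lists need an alphabet")
        perms = [Permutation.from_cycles(alphabet, part, label=f"g{k}")
                 for k, part in enumerate(spec.split(","))]
        return GroupAction(alphabet, perms, spec)
    if ":" in spec:
        head, _, cyc = spec.partition(":")
        letters = [c.strip() for c in cyc.replace(">", " ").split()]
        if letters[0] == letters[-1]:
            letters = letters[:-1]
        if alphabet is None:
            alphabet = default_alphabet(len(letters))
        if not head.upper().startswith("Z") or int(head[1:]) != len(letters):
            raise ValueError(f"cycle length does not match {head!r}")
        gen = Permutation.from_cycle_letters(alphabet, letters)
        return build_cyclic(cycle=gen, alphabet=alphabet, label_prefix="s", name=head.upper())
    parts = [p for p in upper.split("X") if p]
    orders = []
    for p in parts:
        if not p.startswith("Z") or not p[1:].isdigit():
            raise ValueError(f"cannot parse group spec {spec!r}")
        orders.append(int(p[1:]))
    if len(orders) == 1:
        r = orders[0]
        if r == 4 and (alphabet is None or alphabet == DNA):
            return z4_dna()
        if alphabet is None:
            alphabet = default_alphabet(r)
        return build_cyclic(alphabet=alphabet, name=f"Z{r}")
    return build_from_construction(orders, alphabet=alphabet)


def permutation_to_tsv(p: Permutation, alphabet: Alphabet) -> str:
    """Dense 0/1 table with alphabet headers, sources on rows."""
    header = "\t" + "\t".join(alphabet.letters)
    rows = []
    m = p.matrix
    for i, letter in enumerate(alphabet.letters):
        rows.append(letter + "\t" + "\t".join(str(int(x)) for x in m[i]))
    return "\n".join([header] + rows) + "\n"
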