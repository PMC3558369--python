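"""Auditing substitution models for compatibility with the OSM framework.

A substitution model fits the one-step-mutation construction when its
transition matrix is a convex combination of permutation matrices that,
together with the identity, form an Abelian group acting regularly on
the states.  Birkhoff's theorem settles the first half: a matrix is
doubly stochastic iff it decomposes as a convex sum of permutations.
The group conditions are then checked on the extracted permutation set.

The symmetric GTR model (uniform stationary distribution) is the
instructive failure case: its transition matrix decomposes — the six
exchangeability parameters weight the six transpositions of two states —
but the transposition set is not closed, not commutative, and not
fixed-point free, so no OSM matrix can be built from it.  Models with
non-uniform stationary distributions (Tamura-Nei and the like) are not
even doubly stochastic and fail at the decomposition stage.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import maximum_bipartite_matching

from .groups import (
    DNA,
    Alphabet,
    ConditionReport,
    Permutation,
    check_conditions,
)

__all__ = [
    "BirkhoffDecomposition",
    "ModelAudit",
    "is_doubly_stochastic",
    "birkhoff_decompose",
    "audit_model",
    "sgtr_permutation_set",
    "sgtr_matrix",
    "read_matrix_tsv",
]

DEFAULT_TOL = 1e-9


def is_doubly_stochastic(m: np.ndarray, tol: float = DEFAULT_TOL):
    """Check row/column sums; returns (ok, message-or-None naming the offender)."""
    m = np.asarray(m, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        return False, f"matrix is not square: shape {m.shape}"
    if m.min() < -tol:
        i, j = np.unravel_index(int(m.argmin()), m.shape)
        return False, f"negative entry at ({i},{j}): {m[i, j]:g}"
    rows = m.sum(axis=1)
    cols = m.sum(axis=0)
    bad_r = int(np.abs(rows - 1).argmax())
    if abs(rows[bad_r] - 1) > tol:
        return False, f"row {bad_r} sums to {rows[bad_r]:.12g}, not 1"
    bad_c = int(np.abs(cols - 1).argmax())
    if abs(cols[bad_c] - 1) > tol:
        return False, f"column {bad_c} sums to {cols[bad_c]:.12g}, not 1"
    return True, None


@dataclass
class BirkhoffDecomposition:
    """A convex combination of permutation matrices reproducing a doubly stochastic matrix.

    The decomposition is not unique; only the reconstruction (weighted sum
    equals the input) is contractual.
    """

    terms: list  # (weight, Permutation) pairs
    residual: float

    @property
    def weights(self) -> np.ndarray:
        return np.array([w for w, _ in self.terms])

    @property
    def permutations(self) -> list:
        return [p for _, p in self.terms]

    def reconstruct(self) -> np.ndarray:
        r = self.terms[0][1].size
        m = np.zeros((r, r))
        for w, p in self.terms:
            m[np.arange(r), p.mapping] += w
        return m


def _bottleneck_matching(residual: np.ndarray, tol: float) -> np.ndarray | None:
    """Perfect matching on the positive support maximizing the minimum covered entry."""
    support_vals = np.unique(residual[residual > tol])
    if support_vals.size == 0:
        return None

    def match_at(threshold: float):
        mask = sp.csr_matrix(residual >= threshold)
        match = maximum_bipartite_matching(mask, perm_type="column")
        return match if (match >= 0).all() else None

    lo, hi = 0, support_vals.size - 1
    best = match_at(support_vals[0])
    if best is None:
        return None
    while lo < hi:  # largest threshold still admitting a perfect matching
        mid = (lo + hi + 1) // 2
        m = match_at(support_vals[mid])
        if m is not None:
            best, lo = m, mid
        else:
            hi = mid - 1
    return best


def birkhoff_decompose(m: np.ndarray, tol: float = DEFAULT_TOL,
                       max_terms: int | None = None) -> BirkhoffDecomposition:
    """Greedy Birkhoff-von Neumann decomposition of a doubly stochastic matrix.

    Each step extracts a permutation supported on the remaining positive
    entries — chosen to maximize the smallest entry it covers — and
    subtracts it with the minimal covered entry as weight.  At least one
    entry is zeroed per step, so at most (r-1)^2 + 1 terms are produced.
    """
    m = np.asarray(m, dtype=float)
    ok, msg = is_doubly_stochastic(m, tol)
    if not ok:
        raise ValueError(f"not doubly stochastic: {msg}")
    r = m.shape[0]
    residual = m.copy()
    if max_terms is None:
        max_terms = (r - 1) ** 2 + 1 + r  # slack for float noise
    terms = []
    k = 0
    while residual.max() > tol:
        if k >= max_terms:
            raise RuntimeError("decomposition did not terminate; matrix numerically degenerate")
        match = _bottleneck_matching(residual, tol)
        if match is None:
            raise ValueError("no perfect matching in the positive support; "
                             "matrix numerically degenerate")
        p = Permutation(tuple(int(x) for x in match), f"b{len(terms) + 1}")
        w = float(residual[np.arange(r), p.mapping].min())
        residual[np.arange(r), p.mapping] -= w
        terms.append((w, p))
        k += 1
    np.clip(residual, 0, None, out=residual)
    return BirkhoffDecomposition(terms, float(np.abs(residual).max()))


@dataclass
class ModelAudit:
    """Outcome of auditing one transition matrix."""

    doubly_stochastic: bool
    verdict: str  # "admissible" | "group_conditions_violated" | "not_decomposable"
    decomposition: BirkhoffDecomposition | None
    report: ConditionReport | None
    detail: str | None = None

    def to_dict(self) -> dict:
        out = {
            "doubly_stochastic": self.doubly_stochastic,
            "verdict": self.verdict,
            "detail": self.detail,
        }
        if self.decomposition is not None:
            out["n_terms"] = len(self.decomposition.terms)
            out["weights"] = [w for w, _ in self.decomposition.terms]
            out["permutations"] = [list(p.mapping) for _, p in self.decomposition.terms]
            out["residual"] = self.decomposition.residual
        if self.report is not None:
            out["conditions"] = self.report.to_dict()
        return out

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), **kw)

    def __str__(self) -> str:
        lines = [f"doubly stochastic: {self.doubly_stochastic}"]
        if self.detail:
            lines.append(self.detail)
        if self.decomposition is not None:
            lines.append(f"Birkhoff terms: {len(self.decomposition.terms)} "
                         f"(residual {self.decomposition.residual:.3g})")
        if self.report is not None:
            lines.append(str(self.report))
        lines.append(f"verdict: {self.verdict}")
        return "\n".join(lines)


def audit_model(m: np.ndarray, alphabet: Alphabet | None = None,
                tol: float = DEFAULT_TOL) -> ModelAudit:
    """Full OSM-compatibility audit of a transition matrix.

    If the matrix is doubly stochastic it is Birkhoff-decomposed and the
    extracted permutations (plus the identity) are checked against the
    group conditions C1-C7.  All findings land in the report; nothing is
    raised for incompatible models.
    """
    m = np.asarray(m, dtype=float)
    ok, msg = is_doubly_stochastic(m, tol)
    if not ok:
        return ModelAudit(False, "not_decomposable", None, None,
                          detail=f"no convex decomposition into permutations exists: {msg}")
    decomp = birkhoff_decompose(m, tol)
    perms = list(dict.fromkeys(decomp.permutations))  # dedupe, keep order
    ident = Permutation.identity(m.shape[0], "s0")
    if ident not in perms:
        perms.insert(0, ident)
    else:
        perms = [ident] + [p for p in perms if not p.is_identity]
    report = check_conditions(perms, alphabet)
    verdict = "admissible" if report.ok else "group_conditions_violated"
    return ModelAudit(True, verdict, decomp, report)


# ---------------------------------------------------------------------------
# the symmetric GTR reference case


def sgtr_permutation_set() -> dict:
    """The identity plus the six transpositions weighted by the sGTR parameters a..f.

    ``s_a`` swaps A and C, ``s_b`` A/G, ``s_c`` A/T, ``s_d`` C/G,
    ``s_e`` C/T, ``s_f`` G/T, over the alphabet A,C,G,T.
    """
    pairs = {"sa": "AC", "sb": "AG", "sc": "AT", "sd": "CG", "se": "CT", "sf": "GT"}
    out = {"s0": Permutation.identity(4, "s0")}
    for label, (x, y) in pairs.items():
        m = list(range(4))
        i, j = DNA.index(x), DNA.index(y)
        m[i], m[j] = j, i
        out[label] = Permutation(tuple(m), label)
    return out


def sgtr_matrix(a: float, b: float, c: float, d: float, e: float, f: float) -> np.ndarray:
    """The sGTR transition matrix over A,C,G,T with exchangeabilities a..f.

    Doubly stochastic for any nonnegative parameters with row sums ≤ 1;
    equals the convex sum a·s_a + ... + f·s_f (plus no identity mass)
    exactly when a+b+c+d+e+f = 1.
    """
    return np.array([
        [1 - a - b - c, a, b, c],
        [a, 1 - a - d - e, d, e],
        [b, d, 1 - b - d - f, f],
        [c, e, f, 1 - c - e - f],
    ])


def read_matrix_tsv(text: str):
    """Read a square matrix from TSV with alphabet letters as header row and column."""
    rows = [line.split("\t") for line in text.strip().splitlines() if line.strip()]
    header = [h for h in rows[0] if h.strip()]
    letters = tuple(h.strip() for h in header)
    body = rows[1:]
    if len(body) != len(letters):
        raise ValueError(f"expected {len(letters)} data rows, found {len(body)}")
    m = np.empty((len(letters), len(letters)))
    for i, row in enumerate(body):
        if row[0].strip() != letters[i]:
            raise ValueError(f"row label {row[0]!r} does not match header {letters[i]!r}")
        m[i] = [float(x) for x in row[1:len(letters) + 1]]
    return m, Alphabet(letters)
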