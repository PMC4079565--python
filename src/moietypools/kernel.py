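"""Exact left null space of a stoichiometric matrix.

The left kernel {w : w^T xi = 0} contains every conservation law of the
network; its dimension upper-bounds the number of linearly independent
semi-positive conservation laws, and the union of supports of any kernel
basis contains the support of every moiety conservation law.  Everything here
runs over exact rationals — no tolerance, no floating point — because whether
a vector annihilates the matrix is a yes/no question that a genome-scale
model's mixed stoichiometries (1/50 and the like) would otherwise blur.

All-zero metabolite rows (species that take part in no reaction) are excluded
from the kernel computation and reported separately as trivial singleton
conserved species: conserved pools of interest have size >= 2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Dict, List, Sequence, Set

from .model_io import StoichiometricModel

__all__ = [
    "KernelBasis",
    "left_kernel",
    "candidate_metabolites",
    "spcl_bound",
    "nullspace_sparse",
    "covered_kernel_dim",
]

SparseVec = Dict[str, Fraction]


@dataclass
class KernelBasis:
    """Exact rational basis of the left null space.

    ``vectors[i]`` maps metabolite id -> coefficient (nonzeros only); each
    vector annihilates every reaction column exactly.  ``zero_rows`` lists
    metabolites that appear in no reaction (trivial singleton conserved
    species, excluded from the basis).
    """

    vectors: List[SparseVec]
    zero_rows: List[str] = field(default_factory=list)

    @property
    def dim(self) -> int:
        return len(self.vectors)

    def support_union(self) -> Set[str]:
        out: Set[str] = set()
        for v in self.vectors:
            out.update(v)
        return out


def nullspace_sparse(
    rows: Sequence[Dict[int, Fraction]],
    n_vars: int,
    pivoting: str = "scaled",
) -> List[Dict[int, Fraction]]:
    """Basis of {x : A x = 0} for a sparse rational system, by Gaussian
    elimination.

    Parameters
    ----------
    rows : sequence of {column index -> Fraction}
        The equations (nonzero entries only).
    n_vars : int
        Number of unknowns (columns 0..n_vars-1).
    pivoting : {"scaled", "first"}
        "scaled" — scaled partial pivoting: within the current equation, pick
        the entry maximizing |entry| / max|entry in equation|, ties broken by
        lowest column index; equations are processed in order of increasing
        index.  "first" — plain first-nonzero pivoting with reversed column
        preference; an intentionally different elimination order used as an
        independent cross-check.
    """
    # Work on copies; eliminate equation by equation, recording pivot columns.
    eqs = [dict(r) for r in rows if r]
    pivots: Dict[int, Dict[int, Fraction]] = {}  # pivot col -> normalized equation

    def reduce_eq(eq: Dict[int, Fraction]) -> Dict[int, Fraction]:
        for col in sorted(set(eq) & set(pivots)):
            c = eq.get(col)
            if not c:
                continue
            piv = pivots[col]
            for j, v in piv.items():
                nv = eq.get(j, Fraction(0)) - c * v
                if nv:
                    eq[j] = nv
                else:
                    eq.pop(j, None)
        return eq

    order = range(len(eqs))
    for i in order:
        eq = reduce_eq(eqs[i])
        if not eq:
            continue
        if pivoting == "scaled":
            rowmax = max(abs(v) for v in eq.values())
            pivot_col = min(
                (c for c in eq),
                key=lambda c: (-abs(eq[c]) / rowmax, c),
            )
        elif pivoting == "first":
            pivot_col = max(eq)
        else:
            raise ValueError(f"unknown pivoting {pivoting!r}")
        pv = eq[pivot_col]
        norm = {j: v / pv for j, v in eq.items()}
        # back-substitute the new pivot into previously stored equations
        for col, stored in list(pivots.items()):
            c = stored.get(pivot_col)
            if c:
                for j, v in norm.items():
                    nv = stored.get(j, Fraction(0)) - c * v
                    if nv:
                        stored[j] = nv
                    else:
                        stored.pop(j, None)
        pivots[pivot_col] = norm
    free_cols = [c for c in range(n_vars) if c not in pivots]
    basis: List[Dict[int, Fraction]] = []
    for f in free_cols:
        vec: Dict[int, Fraction] = {f: Fraction(1)}
        for col, eqn in pivots.items():
            c = eqn.get(f)
            if c:
                vec[col] = -c
        basis.append(vec)
    return basis


def _integerize(vec: Dict[int, Fraction]) -> Dict[int, Fraction]:
    """Scale a rational vector to coprime integers with positive leading sign."""
    from math import gcd, lcm

    if not vec:
        return vec
    mult = lcm(*(v.denominator for v in vec.values()))
    ints = {k: v * mult for k, v in vec.items()}
    g = 0
    for v in ints.values():
        g = gcd(g, int(v))
    if g > 1:
        ints = {k: v / g for k, v in ints.items()}
    lead = ints[min(ints)]
    if lead < 0:
        ints = {k: -v for k, v in ints.items()}
    return ints


def left_kernel(
    model: StoichiometricModel, pivoting: str = "scaled"
) -> KernelBasis:
    """Exact rational basis of {w : w^T xi = 0}.

    Deterministic given the model's row/column ordering; every returned vector
    is verified against every reaction column before the basis is emitted.
    """
    rows = model.rows()
    active = [m for m in model.metabolite_ids if rows[m]]
    zero_rows = [m for m in model.metabolite_ids if not rows[m]]
    idx = {m: i for i, m in enumerate(active)}
    # equations: one per reaction column r:  sum_m xi_mr w_m = 0
    eq_by_rxn: Dict[str, Dict[int, Fraction]] = {r: {} for r in model.reaction_ids}
    for m in active:
        for r, v in rows[m].items():
            eq_by_rxn[r][idx[m]] = v
    eqs = [eq_by_rxn[r] for r in model.reaction_ids if eq_by_rxn[r]]
    basis_idx = nullspace_sparse(eqs, len(active), pivoting=pivoting)
    vectors: List[SparseVec] = []
    for vec in basis_idx:
        vec = _integerize(vec)
        named = {active[i]: v for i, v in vec.items()}
        vectors.append(named)
    _verify_kernel(model, vectors)
    return KernelBasis(vectors=vectors, zero_rows=zero_rows)


def _verify_kernel(model: StoichiometricModel, vectors: List[SparseVec]) -> None:
    cols = model.columns()
    for w in vectors:
        for r, col in cols.items():
            s = sum((w.get(m, Fraction(0)) * v for m, v in col.items()), Fraction(0))
            if s != 0:
                raise AssertionError(f"kernel vector fails to annihilate column {r}")


def candidate_metabolites(kern: KernelBasis) -> Set[str]:
    """Union of supports of the kernel basis vectors.

    Every conserved pool's coefficient vector lies in the kernel span, hence
    vanishes outside this union: the search for pools can be confined to it.
    """
    return kern.support_union()


def spcl_bound(kern: KernelBasis) -> int:
    """Upper bound on the number of linearly independent semi-positive
    conservation laws (= kernel dimension); the saturation stopping
    criterion of the search driver."""
    return kern.dim


def covered_kernel_dim(model: StoichiometricModel, covered: Set[str]) -> int:
    """Dimension of the left kernel restricted to vectors supported inside
    ``covered`` (i.e. the left kernel of the row-submatrix).

    Used by the completeness certificate: once the uncovered candidates are
    proven pool-free, every remaining conserved pool lives in this subspace,
    so a basis whose rank equals this dimension spans all of them.
    """
    rows = model.rows()
    active = [m for m in model.metabolite_ids if m in covered and rows[m]]
    idx = {m: i for i, m in enumerate(active)}
    eq_by_rxn: Dict[str, Dict[int, Fraction]] = {}
    for m in active:
        for r, v in rows[m].items():
            eq_by_rxn.setdefault(r, {})[idx[m]] = v
    basis = nullspace_sparse(list(eq_by_rxn.values()), len(active))
    return len(basis)
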