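"""Metropolis-annealing extraction of moiety conservation laws.

A moiety conservation law (MCL) is a non-negative integer vector k, gcd 1 on
its support, with k^T xi = 0.  Finding one is mapped to finding a ground
state of the discrete energy

    E(k) = sum_r ( sum_m xi_mr k_m )^2

which is zero exactly when k balances every reaction.  A Metropolis chain
over k in {0..k_max}^candidates samples exp(-E/T); slowly lowering T
(annealing) drives it into the E=0 set.  The all-zero vector trivially has
E=0, so each annealing run "pins" one target metabolite to k >= 1, which both
excludes the trivial solution and steers the chain toward a small pool
containing the pin.

Superpositions of independent pools are themselves E=0 states; they are
reduced by iteratively subtracting known basis pools while keeping all
coefficients non-negative, and linear dependencies among the survivors are
resolved by exact rational elimination.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from fractions import Fraction
from math import exp, gcd
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

from .model_io import StoichiometricModel

__all__ = [
    "IntegerPool",
    "PoolBasis",
    "AnnealConfig",
    "RationalSpan",
    "energy",
    "metropolis_anneal",
    "MetropolisChain",
    "reduce_superposition",
    "assemble_basis",
]


@dataclass(frozen=True)
class IntegerPool:
    """A conserved pool: metabolite -> positive integer coefficient.

    Invariants: non-empty support, all coefficients >= 1, gcd over the
    support = 1, and sum_m k_m xi_mr = 0 for every reaction (checked by
    :meth:`verify`).
    """

    coeffs: Tuple[Tuple[str, int], ...]

    @staticmethod
    def from_dict(d: Dict[str, int]) -> "IntegerPool":
        items = {m: int(k) for m, k in d.items() if k}
        if not items:
            raise ValueError("empty pool")
        if any(k < 0 for k in items.values()):
            raise ValueError("negative pool coefficient")
        g = 0
        for k in items.values():
            g = gcd(g, k)
        return IntegerPool(tuple(sorted((m, k // g) for m, k in items.items())))

    @property
    def coeffs_dict(self) -> Dict[str, int]:
        return dict(self.coeffs)

    @property
    def support(self) -> Set[str]:
        return {m for m, _ in self.coeffs}

    @property
    def size(self) -> int:
        return len(self.coeffs)

    def verify(self, model: StoichiometricModel) -> bool:
        """Exact rational check that the pool balances every reaction."""
        cols = model.columns()
        kd = self.coeffs_dict
        for col in cols.values():
            s = sum((Fraction(kd.get(m, 0)) * v for m, v in col.items()), Fraction(0))
            if s != 0:
                return False
        return True

    # dict-like conveniences used throughout
    def __getitem__(self, m: str) -> int:
        return self.coeffs_dict.get(m, 0)


@dataclass
class PoolBasis:
    """Ordered, linearly independent (over the rationals) set of pools."""

    pools: List[IntegerPool] = field(default_factory=list)

    @property
    def covered(self) -> Set[str]:
        out: Set[str] = set()
        for p in self.pools:
            out.update(p.support)
        return out

    def __len__(self) -> int:
        return len(self.pools)

    def __iter__(self):
        return iter(self.pools)


@dataclass
class AnnealConfig:
    """Annealing schedule and search bounds.

    k_max
        Coefficient cap during a run; the driver escalates it (doubling, up
        to ``k_max_limit``) for pins that fail every restart, since columns
        integerized from 1/50-style stoichiometries need large coefficients.
    T0, cooling, T_min
        Geometric schedule: T <- cooling * T from T0 down to T_min.
    sweeps_per_T
        Number of single-coordinate proposals per temperature level; if None,
        10 * |candidates| is used.
    restarts
        Independent seeded restarts per pin before giving up.
    patience
        Abort a restart after this many consecutive temperature levels
        without an improvement of the best energy seen (the chain has frozen
        away from a ground state); None runs every schedule to T_min.
    """

    k_max: int = 4
    T0: float = 2.0
    cooling: float = 0.95
    sweeps_per_T: Optional[int] = None
    T_min: float = 1e-3
    restarts: int = 20
    seed: int = 0
    k_max_limit: int = 64
    energy_form: str = "squared"  # or "abs"
    patience: Optional[int] = 25

    def __post_init__(self) -> None:
        if not (0 < self.cooling < 1):
            raise ValueError("cooling must be in (0,1)")
        if min(self.k_max, self.T0, self.T_min, self.restarts) <= 0:
            raise ValueError("k_max, T0, T_min, restarts must be positive")


def energy(k: Dict[str, int], model: StoichiometricModel, form: str = "squared") -> Fraction:
    """E(k): summed squared (or absolute) per-reaction residual; zero iff k
    balances every column."""
    total = Fraction(0)
    for col in model.columns().values():
        s = sum((Fraction(k.get(m, 0)) * v for m, v in col.items()), Fraction(0))
        total += s * s if form == "squared" else abs(s)
    return total


# ---------------------------------------------------------------------------
# The chain
# ---------------------------------------------------------------------------


class MetropolisChain:
    """Single-coordinate ±1 Metropolis dynamics on integer coefficient vectors.

    Works on an integer model (run clear_denominators first).  The chain is
    exposed as a class so that fixed-temperature sampling (used to verify
    detailed balance against the Boltzmann distribution) shares the exact
    code path used by the annealer.
    """

    def __init__(
        self,
        model: StoichiometricModel,
        candidates: Sequence[str],
        k_max: int,
        pinned: Optional[str] = None,
        rng: Optional[random.Random] = None,
        energy_form: str = "squared",
    ):
        if not model.is_integer():
            raise ValueError("MetropolisChain requires an integer matrix; run clear_denominators")
        self.candidates = list(candidates)
        self.k_max = k_max
        self.pinned = pinned
        self.rng = rng or random.Random(0)
        self.energy_form = energy_form
        rows = model.rows()
        # adjacency restricted to candidates; reactions touched by candidates
        rxn_ids: List[str] = []
        rxn_idx: Dict[str, int] = {}
        self._adj: List[List[Tuple[int, int]]] = []  # candidate index -> [(rxn idx, coeff)]
        for m in self.candidates:
            lst = []
            for r, v in rows[m].items():
                if r not in rxn_idx:
                    rxn_idx[r] = len(rxn_ids)
                    rxn_ids.append(r)
                lst.append((rxn_idx[r], int(v)))
            self._adj.append(lst)
        self.n_rxns = len(rxn_ids)
        self._ki: List[int] = [0] * len(self.candidates)
        self._pin_idx = None
        if pinned is not None:
            try:
                self._pin_idx = self.candidates.index(pinned)
            except ValueError:
                raise ValueError(f"pinned metabolite {pinned!r} not in candidate set") from None
            self._ki[self._pin_idx] = 1
        self.resid = [0] * self.n_rxns
        for i, km in enumerate(self._ki):
            if km:
                for r, v in self._adj[i]:
                    self.resid[r] += v * km
        self.E = self._full_energy()

    @property
    def adj(self) -> Dict[str, List[Tuple[int, int]]]:
        return {m: self._adj[i] for i, m in enumerate(self.candidates)}

    @property
    def k(self) -> Dict[str, int]:
        return {m: self._ki[i] for i, m in enumerate(self.candidates)}

    def _full_energy(self) -> int:
        if self.energy_form == "squared":
            return sum(s * s for s in self.resid)
        return sum(abs(s) for s in self.resid)

    def step(self, T: float) -> None:
        """One proposal: random candidate, ±1, accept with min(1, e^(-dE/T))."""
        rnd = self.rng.random
        n = len(self.candidates)
        i = int(rnd() * n)
        delta = 1 if rnd() < 0.5 else -1
        ki = self._ki
        new = ki[i] + delta
        lo = 1 if i == self._pin_idx else 0
        if new < lo or new > self.k_max:
            return
        resid = self.resid
        adj_i = self._adj[i]
        dE = 0
        if self.energy_form == "squared":
            for r, v in adj_i:
                s = resid[r]
                dv = delta * v
                dE += dv * (2 * s + dv)
        else:
            for r, v in adj_i:
                s = resid[r]
                dE += abs(s + delta * v) - abs(s)
        if dE <= 0 or rnd() < exp(-dE / T):
            ki[i] = new
            for r, v in adj_i:
                resid[r] += delta * v
            self.E += dE

    def state(self) -> Tuple[int, ...]:
        return tuple(self._ki)


def metropolis_anneal(
    model: StoichiometricModel,
    pinned: str,
    cfg: AnnealConfig,
    candidates: Optional[Sequence[str]] = None,
) -> Optional[IntegerPool]:
    """Anneal toward a zero-energy state with k_pinned >= 1.

    Returns the first visited E=0 state (gcd-canonicalized) or None if no
    zero-energy state is reached across all restarts.  Moves are restricted
    to ``candidates`` (default: all metabolites with at least one reaction).
    """
    if candidates is None:
        rows = model.rows()
        candidates = [m for m in model.metabolite_ids if rows[m]]
    if pinned not in set(candidates):
        raise ValueError(f"pinned metabolite {pinned!r} not in candidate set")
    n = len(candidates)
    sweeps = cfg.sweeps_per_T if cfg.sweeps_per_T is not None else 10 * n
    for restart in range(cfg.restarts):
        rng = random.Random((cfg.seed * 1000003 + restart * 8191) % (2**31))
        chain = MetropolisChain(
            model, candidates, cfg.k_max, pinned=pinned, rng=rng,
            energy_form=cfg.energy_form,
        )
        if chain.E == 0:
            return IntegerPool.from_dict(chain.k)
        T = cfg.T0
        best_E = chain.E
        stale = 0
        while T > cfg.T_min:
            for _ in range(sweeps):
                chain.step(T)
                if chain.E == 0:
                    pool = IntegerPool.from_dict(chain.k)
                    assert pool.verify(model)
                    return pool
            if chain.E < best_E:
                best_E = chain.E
                stale = 0
            else:
                stale += 1
                if cfg.patience is not None and stale >= cfg.patience:
                    break  # frozen away from a ground state; restart
            T *= cfg.cooling
    return None


# ---------------------------------------------------------------------------
# Reduction and basis assembly
# ---------------------------------------------------------------------------


def reduce_superposition(pool: IntegerPool, basis: PoolBasis) -> Optional[IntegerPool]:
    """Strip known pools out of a zero-energy state.

    Repeatedly subtracts the largest integer multiple of each basis pool that
    keeps every coefficient non-negative, cycling until no subtraction
    applies.  Because the balance constraint is linear, each remainder is
    itself a valid conserved vector.  Returns the gcd-canonical remainder, or
    None if the state was a non-negative integer combination of basis pools.
    """
    k = pool.coeffs_dict
    changed = True
    while changed:
        changed = False
        for b in basis:
            bd = b.coeffs_dict
            t = min(k.get(m, 0) // kb for m, kb in bd.items())
            if t >= 1:
                for m, kb in bd.items():
                    k[m] -= t * kb
                    if k[m] == 0:
                        del k[m]
                changed = True
        if not k:
            return None
    return IntegerPool.from_dict(k)


class RationalSpan:
    """Incremental exact rational span with membership/insertion tests."""

    def __init__(self) -> None:
        self._rref: Dict[str, Dict[str, Fraction]] = {}  # pivot metabolite -> row

    def _residual(self, vec: Dict[str, Fraction]) -> Dict[str, Fraction]:
        v = {m: Fraction(x) for m, x in vec.items() if x}
        for piv in sorted(set(v) & set(self._rref)):
            c = v.get(piv)
            if not c:
                continue
            for m, x in self._rref[piv].items():
                nv = v.get(m, Fraction(0)) - c * x
                if nv:
                    v[m] = nv
                else:
                    v.pop(m, None)
        return v

    def contains(self, vec: Dict[str, Fraction]) -> bool:
        return not self._residual(vec)

    def add(self, vec: Dict[str, Fraction]) -> bool:
        """Insert if independent of the current span; returns True if rank grew."""
        res = self._residual(vec)
        if not res:
            return False
        piv = min(res)
        pv = res[piv]
        row = {m: x / pv for m, x in res.items()}
        for p, stored in self._rref.items():
            c = stored.get(piv)
            if c:
                for m, x in row.items():
                    nv = stored.get(m, Fraction(0)) - c * x
                    if nv:
                        stored[m] = nv
                    else:
                        stored.pop(m, None)
        self._rref[piv] = row
        return True

    @property
    def rank(self) -> int:
        return len(self._rref)


def assemble_basis(pools: Iterable[IntegerPool], kern) -> PoolBasis:
    """Deduplicate and greedily admit pools in discovery order, rejecting any
    vector rationally dependent on the admitted ones; the result never
    exceeds the kernel-dimension bound."""
    span = RationalSpan()
    basis = PoolBasis()
    seen: Set[Tuple[Tuple[str, int], ...]] = set()
    for p in pools:
        if p.coeffs in seen:
            continue
        seen.add(p.coeffs)
        vec = {m: Fraction(k) for m, k in p.coeffs}
        if span.add(vec):
            basis.pools.append(p)
    if kern is not None and len(basis) > kern.dim:
        raise AssertionError(
            f"assembled {len(basis)} independent pools but kernel dim is {kern.dim}"
        )
    return basis
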