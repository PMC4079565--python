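"""Annealing search: energy, chain, superposition reduction, basis assembly."""

from __future__ import annotations

import random
from math import exp

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from moietypools.kernel import left_kernel
from moietypools.mc_search import (
    AnnealConfig,
    IntegerPool,
    MetropolisChain,
    PoolBasis,
    assemble_basis,
    energy,
    metropolis_anneal,
    reduce_superposition,
)
from moietypools.random_ensemble import plant_pools


class TestEnergy:
    def test_zero_vector_has_zero_energy(self, ab_reaction):
        assert energy({}, ab_reaction) == 0

    def test_valid_pool_has_zero_energy(self, toy_enzyme):
        assert energy({"E": 1, "ES": 1}, toy_enzyme) == 0
        assert energy({"S": 1, "ES": 1, "P": 1}, toy_enzyme) == 0

    def test_single_violated_unit_column(self, ab_reaction):
        assert energy({"A": 1}, ab_reaction) == 1
        assert energy({"A": 2}, ab_reaction, form="squared") == 4
        assert energy({"A": 2}, ab_reaction, form="abs") == 2


class TestIntegerPool:
    def test_gcd_canonicalization(self):
        p = IntegerPool.from_dict({"a": 4, "b": 6})
        assert p.coeffs_dict == {"a": 2, "b": 3}

    @given(st.dictionaries(st.sampled_from("abcde"),
                           st.integers(min_value=0, max_value=30), min_size=1))
    @settings(deadline=None)
    def test_canonicalization_idempotent(self, coeffs):
        if not any(coeffs.values()):
            coeffs["a"] = 1
        p = IntegerPool.from_dict(coeffs)
        assert IntegerPool.from_dict(p.coeffs_dict) == p
        g = 0
        for k in p.coeffs_dict.values():
            g = np.gcd(g, k)
        assert g == 1

    def test_verify_is_exact(self, toy_enzyme):
        assert IntegerPool.from_dict({"E": 1, "ES": 1}).verify(toy_enzyme)
        assert not IntegerPool.from_dict({"E": 1, "S": 1}).verify(toy_enzyme)


class TestAnneal:
    def test_single_reaction(self, ab_reaction):
        pool = metropolis_anneal(ab_reaction, "A", AnnealConfig(seed=1))
        assert pool.coeffs_dict == {"A": 1, "B": 1}

    def test_closed_two_cycle(self, two_cycle):
        pool = metropolis_anneal(two_cycle, "A", AnnealConfig(seed=2))
        assert pool.coeffs_dict == {"A": 1, "B": 1}

    def test_pin_outside_candidates_rejected(self, ab_reaction):
        with pytest.raises(ValueError, match="pinned"):
            metropolis_anneal(ab_reaction, "Z", AnnealConfig(seed=0))

    def test_planted_pool_recovery_rate(self):
        """A planted pool must be recovered from a pinned member in almost
        every seeded run (the fixture construction makes it the unique
        canonical pool through the pin)."""
        model, truth = plant_pools(
            30, 45, [{"X": 1, "Y": 2, "Z": 1}], c=1.5, seed=9
        )
        hits = 0
        runs = 100
        for s in range(runs):
            pool = metropolis_anneal(model, "X", AnnealConfig(seed=s))
            hits += pool is not None and pool == truth.pools[0]
        assert hits >= 95


def test_detailed_balance_at_fixed_temperature(ab_reaction):
    """Long fixed-T run of the chain must reproduce the Boltzmann weights
    exp(-E/T) over the 9 states of the two-variable system (closed form)."""
    T = 1.0
    k_max = 2
    chain = MetropolisChain(ab_reaction, ["A", "B"], k_max,
                            rng=random.Random(7))
    counts = {}
    burn = 2000
    steps = 400_000
    for i in range(burn + steps):
        chain.step(T)
        if i >= burn:
            s = chain.state()
            counts[s] = counts.get(s, 0) + 1
    states = [(a, b) for a in range(k_max + 1) for b in range(k_max + 1)]
    weights = {s: exp(-float(energy({"A": s[0], "B": s[1]}, ab_reaction)) / T)
               for s in states}
    Z = sum(weights.values())
    for s in states:
        expected = weights[s] / Z
        observed = counts.get(s, 0) / steps
        assert abs(observed - expected) < 0.01, (s, observed, expected)


class TestReduceSuperposition:
    def test_disjoint_sum_reduces_to_none(self):
        basis = PoolBasis(pools=[
            IntegerPool.from_dict({"a": 1, "b": 1}),
            IntegerPool.from_dict({"c": 1, "d": 1}),
        ])
        total = IntegerPool.from_dict({"a": 1, "b": 1, "c": 1, "d": 1})
        assert reduce_superposition(total, basis) is None

    def test_multiple_of_basis_pool_reduces_to_none(self):
        basis = PoolBasis(pools=[IntegerPool.from_dict({"a": 1, "b": 2})])
        assert reduce_superposition(IntegerPool.from_dict({"a": 2, "b": 4}), basis) is None

    def test_overlapping_pools_reduce_to_the_other(self):
        # archetype: two pools sharing one species; their sum reduced by one
        # yields the other
        p1 = IntegerPool.from_dict({"shared": 1, "x1": 1, "x2": 1})
        p2 = IntegerPool.from_dict({"shared": 1, "y1": 1, "y2": 1})
        total = IntegerPool.from_dict({"shared": 2, "x1": 1, "x2": 1, "y1": 1, "y2": 1})
        out = reduce_superposition(total, PoolBasis(pools=[p1]))
        assert out == p2

    def test_irreducible_pool_returned_canonical(self):
        basis = PoolBasis(pools=[IntegerPool.from_dict({"a": 1, "b": 1})])
        p = IntegerPool.from_dict({"c": 2, "d": 2})
        assert reduce_superposition(p, basis) == IntegerPool.from_dict({"c": 1, "d": 1})


class TestAssembleBasis:
    def test_duplicates_collapse(self, ab_reaction):
        kern = left_kernel(ab_reaction)
        p = IntegerPool.from_dict({"A": 1, "B": 1})
        basis = assemble_basis([p, p, p], kern)
        assert len(basis) == 1

    def test_dependent_triple_has_rank_two(self):
        pools = [
            IntegerPool.from_dict({"a": 1, "b": 1}),
            IntegerPool.from_dict({"b": 1, "c": 1}),
            IntegerPool.from_dict({"a": 1, "b": 2, "c": 1}),  # = first + second
        ]
        basis = assemble_basis(pools, None)
        assert [p.coeffs_dict for p in basis] == [
            {"a": 1, "b": 1}, {"b": 1, "c": 1},
        ]

    def test_kernel_bound_enforced(self, ab_reaction):
        kern = left_kernel(ab_reaction)  # dim 1
        pools = [
            IntegerPool.from_dict({"A": 1, "B": 1}),
            IntegerPool.from_dict({"A": 1, "B": 2}),  # not a pool, but independent
        ]
        with pytest.raises(AssertionError):
            assemble_basis(pools, kern)
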