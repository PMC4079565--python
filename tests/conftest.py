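"""Shared fixtures and oracle helpers.

Everything here is generated programmatically; the brute-force enumeration
in :mod:`moietypools.random_ensemble` and the independent implementations in
this file serve as ground truth for the stochastic components.
"""

from __future__ import annotations

import itertools
from fractions import Fraction

import pytest

from moietypools import fixtures as fx
from moietypools.mc_search import RationalSpan
from moietypools.model_io import StoichiometricModel, detect_exchanges


@pytest.fixture
def toy_enzyme():
    return fx.toy_enzyme_network()


@pytest.fixture
def ab_reaction():
    return fx.single_reaction()


@pytest.fixture
def two_cycle():
    return fx.closed_two_cycle()


def make_model(entries, provenance="test"):
    """Build a model from {(met, rxn): coeff} with ids in insertion order."""
    mets, rxns = [], []
    for m, r in entries:
        if m not in mets:
            mets.append(m)
        if r not in rxns:
            rxns.append(r)
    coeff = {k: Fraction(v) for k, v in entries.items()}
    return StoichiometricModel(
        metabolite_ids=mets,
        reaction_ids=rxns,
        coeff=coeff,
        exchange_ids=detect_exchanges(mets, rxns, coeff),
        provenance=provenance,
    )


def enumerate_solutions(model, k_max):
    """Independent exhaustive oracle: all non-zero non-negative integer
    vectors over ALL metabolites (not just kernel candidates) satisfying
    every column balance.  Deliberately naive — itertools product plus a
    per-column rational check — and shared by several oracle tests."""
    mets = model.metabolite_ids
    cols = model.columns()
    sols = []
    for k in itertools.product(range(k_max + 1), repeat=len(mets)):
        if not any(k):
            continue
        kd = dict(zip(mets, k))
        if all(
            sum((Fraction(kd[m]) * v for m, v in col.items()), Fraction(0)) == 0
            for col in cols.values()
        ):
            sols.append(kd)
    return sols


def span_of(pools):
    sp = RationalSpan()
    for p in pools:
        sp.add({m: Fraction(k) for m, k in p.coeffs})
    return sp


def same_span(pools_a, pools_b) -> bool:
    sa, sb = span_of(pools_a), span_of(pools_b)
    if sa.rank != sb.rank:
        return False
    return all(sa.contains({m: Fraction(k) for m, k in p.coeffs}) for p in pools_b)


def coverage_of(pools):
    out = set()
    for p in pools:
        out |= p.support
    return out
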