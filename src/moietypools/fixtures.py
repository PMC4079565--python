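"""Small hand-built stoichiometric networks used in examples and tests.

These are first-class library objects: each returns a fully validated
:class:`~moietypools.model_io.StoichiometricModel` with exact coefficients.
"""

from __future__ import annotations

from fractions import Fraction
from .model_io import StoichiometricModel, detect_exchanges

__all__ = [
    "toy_enzyme_network",
    "single_reaction",
    "closed_two_cycle",
    "open_chain",
    "triangle_pools",
]

F = Fraction


def _model(mets, rxns, entries, provenance) -> StoichiometricModel:
    coeff = {(m, r): F(v) for (m, r), v in entries.items()}
    return StoichiometricModel(
        metabolite_ids=list(mets),
        reaction_ids=list(rxns),
        coeff=coeff,
        exchange_ids=detect_exchanges(mets, rxns, coeff),
        provenance=provenance,
    )


def toy_enzyme_network() -> StoichiometricModel:
    """Three-reaction enzyme toy: E + S <-> ES, ES -> E + P.

    Left kernel has dimension 2; its non-negative integer generators are the
    enzyme mass {E, ES} and the substrate moiety {S, ES, P}.  Other conserved
    quantities (e.g. total mass E + S + 2 ES + P) are combinations of these.
    """
    mets = ["E", "S", "ES", "P"]
    rxns = ["bind", "unbind", "cat"]
    entries = {
        ("E", "bind"): -1, ("S", "bind"): -1, ("ES", "bind"): 1,
        ("E", "unbind"): 1, ("S", "unbind"): 1, ("ES", "unbind"): -1,
        ("ES", "cat"): -1, ("E", "cat"): 1, ("P", "cat"): 1,
    }
    return _model(mets, rxns, entries, "fixture:toy_enzyme")


def single_reaction() -> StoichiometricModel:
    """A -> B: kernel dim 1, unique pool {A:1, B:1}."""
    return _model(["A", "B"], ["r1"], {("A", "r1"): -1, ("B", "r1"): 1},
                  "fixture:single_reaction")


def closed_two_cycle() -> StoichiometricModel:
    """A <-> B as two opposite columns: the closed system whose pool {A, B}
    makes the strict producibility system infeasible (Motzkin alternative)."""
    entries = {("A", "f"): -1, ("B", "f"): 1, ("A", "b"): 1, ("B", "b"): -1}
    return _model(["A", "B"], ["f", "b"], entries, "fixture:closed_two_cycle")


def open_chain() -> StoichiometricModel:
    """uptake -> A -> B -> export: everything producible, empty kernel."""
    entries = {
        ("A", "EX_in"): 1,
        ("A", "conv"): -1, ("B", "conv"): 1,
        ("B", "EX_out"): -1,
    }
    return _model(["A", "B"], ["EX_in", "conv", "EX_out"], entries, "fixture:open_chain")


def triangle_pools() -> StoichiometricModel:
    """Four overlapping pairs on one column: A - B + C - D = 0.

    Kernel dim 3; the canonical minimal pools are the four sign-balanced
    pairs {A,B}, {A,D}, {B,C}, {C,D}, any two disjoint ones of which cover
    all metabolites while spanning only a 2-dim subspace.  Exercises the
    span-gap branch of the completeness certificate: coverage alone is not
    completeness.
    """
    entries = {("A", "r1"): 1, ("B", "r1"): -1, ("C", "r1"): 1, ("D", "r1"): -1}
    return _model(["A", "B", "C", "D"], ["r1"], entries, "fixture:triangle_pools")
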