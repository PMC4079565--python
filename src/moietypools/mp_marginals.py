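"""Sum-product (belief propagation) marginals over the conserved-pool solution space.

The uniform distribution over all solutions of k^T xi = 0 with
k in {0..k_max}^M carries a full statistical picture of the pool structure:
the single-site marginal p_m(k) is the histogram of the m-th coordinate over
the solution set, and 1 - p_m(0) is proportional to the number of distinct
pools the metabolite takes part in.  In particular p_m(0) = 1 exactly when
metabolite m belongs to no pool, so the marginals double as a pruning device
for the downstream Monte Carlo search.

The solution space is represented as a factor graph — variable nodes are
metabolites with domain {0..k_max}; factor nodes are reactions enforcing the
hard linear constraint sum_m xi_mr k_m = 0 — and the marginals are estimated
by damped sum-product message passing.  Factor-to-variable messages are
computed by convolving the incoming messages over the bounded partial-sum
variable s = sum xi k (|s| <= k_max * sum|xi| within a factor), which keeps
each update linear in the factor degree times the window width.

Sum-product is exact on trees and a well-behaved heuristic on loopy graphs;
on loops it can under-count, so the driver takes the union of the BP
candidate set with the kernel-support set when they disagree.  The all-zero
assignment is a valid solution and is deliberately part of the measure, so
marginals never degenerate and pool membership is read from p_m(0) < 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Set, Tuple

import numpy as np

from .model_io import StoichiometricModel

__all__ = [
    "FactorGraph",
    "MarginalTable",
    "build_factor_graph",
    "compute_marginals",
    "prune_by_marginals",
]

logger = logging.getLogger(__name__)


@dataclass
class FactorGraph:
    """Bipartite constraint graph of the pool equations."""

    variables: List[str]                       # metabolite ids
    k_max: int
    factors: List[Tuple[str, List[Tuple[int, int]]]]  # (reaction id, [(var index, coeff)])

    @property
    def degrees(self) -> Dict[str, int]:
        """factor id -> number of participating variables."""
        return {rid: len(terms) for rid, terms in self.factors}


@dataclass
class MarginalTable:
    """Per-metabolite marginals of the uniform solution-space distribution."""

    k_max: int
    p: Dict[str, np.ndarray]
    converged: bool
    iterations: int


def build_factor_graph(model: StoichiometricModel, k_max: int) -> FactorGraph:
    """Variables = metabolites appearing in at least one reaction; one factor
    per non-empty reaction column enforcing its balance."""
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    if not model.is_integer():
        raise ValueError("factor graph requires an integer matrix; run clear_denominators")
    rows = model.rows()
    variables = [m for m in model.metabolite_ids if rows[m]]
    vidx = {m: i for i, m in enumerate(variables)}
    factors: List[Tuple[str, List[Tuple[int, int]]]] = []
    for r, col in model.columns().items():
        if col:
            factors.append((r, [(vidx[m], int(v)) for m, v in col.items()]))
    return FactorGraph(variables=variables, k_max=k_max, factors=factors)


def _factor_message(
    terms: List[Tuple[int, int]],
    incoming: List[np.ndarray],
    skip: int,
    k_max: int,
) -> np.ndarray:
    """Message factor -> variable ``terms[skip][0]``.

    Convolves the incoming messages of the other variables over the partial
    sum s = sum xi k and reads off the weight at s = -xi_skip * k.
    """
    window = sum(abs(c) for _, c in terms) * k_max
    dist = np.zeros(2 * window + 1)
    dist[window] = 1.0  # s = 0
    for j, (v, c) in enumerate(terms):
        if j == skip:
            continue
        msg = incoming[j]
        new = np.zeros_like(dist)
        for k in range(k_max + 1):
            w = msg[k]
            if w == 0.0:
                continue
            shift = c * k
            if shift == 0:
                new += w * dist
            elif shift > 0:
                new[shift:] += w * dist[:-shift]
            else:
                new[:shift] += w * dist[-shift:]
        dist = new
    c0 = terms[skip][1]
    out = np.empty(k_max + 1)
    for k in range(k_max + 1):
        s = -c0 * k
        out[k] = dist[window + s] if abs(s) <= window else 0.0
    return out


def compute_marginals(
    graph: FactorGraph,
    damping: float = 0.5,
    max_iter: int = 10_000,
    tol: float = 1e-8,
    seed: Optional[int] = 0,
) -> MarginalTable:
    """Damped sum-product to a fixed point; returns normalized beliefs.

    Messages are initialized uniform with seeded multiplicative noise (to
    break symmetry on loopy graphs).  Non-convergence within ``max_iter``
    returns converged=False; the caller should then fall back to
    kernel-support pruning.
    """
    if not (0 <= damping < 1):
        raise ValueError("damping must be in [0,1)")
    rng = np.random.default_rng(seed)
    K = graph.k_max
    nv = len(graph.variables)

    # edge lists
    var_edges: List[List[Tuple[int, int]]] = [[] for _ in range(nv)]  # var -> [(factor, slot)]
    for fi, (_, terms) in enumerate(graph.factors):
        for slot, (v, _) in enumerate(terms):
            var_edges[v].append((fi, slot))

    def norm(a: np.ndarray) -> np.ndarray:
        s = a.sum()
        return a / s if s > 0 else np.full_like(a, 1.0 / len(a))

    # messages variable->factor and factor->variable, indexed [factor][slot]
    v2f: List[List[np.ndarray]] = []
    f2v: List[List[np.ndarray]] = []
    for _, terms in graph.factors:
        v2f.append([norm(1.0 + 0.01 * rng.random(K + 1)) for _ in terms])
        f2v.append([np.full(K + 1, 1.0 / (K + 1)) for _ in terms])

    it = 0
    converged = False
    for it in range(1, max_iter + 1):
        delta = 0.0
        # factor -> variable
        for fi, (_, terms) in enumerate(graph.factors):
            for slot in range(len(terms)):
                new = norm(_factor_message(terms, v2f[fi], slot, K))
                mixed = damping * f2v[fi][slot] + (1 - damping) * new
                delta = max(delta, float(np.max(np.abs(mixed - f2v[fi][slot]))))
                f2v[fi][slot] = mixed
        # variable -> factor
        for v in range(nv):
            edges = var_edges[v]
            for fi, slot in edges:
                prod = np.ones(K + 1)
                for fj, sj in edges:
                    if (fj, sj) != (fi, slot):
                        prod *= f2v[fj][sj]
                new = norm(prod)
                mixed = damping * v2f[fi][slot] + (1 - damping) * new
                delta = max(delta, float(np.max(np.abs(mixed - v2f[fi][slot]))))
                v2f[fi][slot] = mixed
        if delta < tol:
            converged = True
            break

    p: Dict[str, np.ndarray] = {}
    for v, m in enumerate(graph.variables):
        belief = np.ones(K + 1)
        for fi, slot in var_edges[v]:
            belief *= f2v[fi][slot]
        p[m] = norm(belief)
    return MarginalTable(k_max=K, p=p, converged=converged, iterations=it)


def prune_by_marginals(table: MarginalTable, threshold: float = 0.0) -> Set[str]:
    """Candidate pool members: metabolites with 1 - p_m(0) > threshold.

    With threshold 0 this is the full BP candidate set.  Loopy graphs can
    make BP under-count; callers comparing against the kernel-support set
    should take the union when the two disagree (logged as a warning by the
    pipeline driver).
    """
    if not table.converged:
        raise ValueError("marginals did not converge; fall back to kernel-support pruning")
    return {m for m, pm in table.p.items() if 1.0 - float(pm[0]) > threshold}
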