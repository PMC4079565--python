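"""Completeness certification by producibility duality, and the top-level driver.

Pool membership and producibility are dual: by Motzkin's transposition
theorem, for any subset R of metabolite rows exactly one of the following
holds — either there is a flux direction v with xi v >= 0 componentwise and
strictly positive entries on R (every metabolite of R is net-producible), or
there is a non-negative integer conservation law with positive weight on
some metabolite of R.  A witness v for the first alternative therefore
proves that no undiscovered pool touches R.

Witnesses are sought with the classic relaxation schemes (MinOver / Motzkin)
that repeatedly correct the least-satisfied inequality; they converge in
polynomial time whenever a solution exists, so a stall within the iteration
budget proves nothing and is reported as "inconclusive", never as success.

A converged witness alone does not certify completeness: an undiscovered
pool supported entirely inside the already-covered metabolites would slip
through.  Certification here additionally requires that the rank of the
assembled basis equal the dimension of the left kernel restricted to the
covered rows — once the uncovered candidates are proven pool-free, every
conservation pool lives in that subspace, and a basis of matching rank spans
it.  The witness itself is re-checked a posteriori in exact rational
arithmetic.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np

from .kernel import KernelBasis, candidate_metabolites, covered_kernel_dim, left_kernel
from .mc_search import (
    AnnealConfig,
    IntegerPool,
    PoolBasis,
    RationalSpan,
    metropolis_anneal,
    reduce_superposition,
)
from .model_io import StoichiometricModel

__all__ = [
    "DualWitness",
    "StallReport",
    "CertificateReport",
    "PipelineConfig",
    "relax_witness",
    "certify_completeness",
    "find_all_mcls",
]

logger = logging.getLogger(__name__)


@dataclass
class DualWitness:
    """A flux direction v with xi v >= 0, strictly positive on the strict set."""

    v: np.ndarray                       # indexed by model.reaction_ids
    margins: Dict[str, float]           # metabolite -> (xi v)_m (unit-normalized rows)
    iterations: int


@dataclass
class StallReport:
    """Relaxation ran out of budget; lists the least-satisfied rows."""

    blockers: List[str]
    iterations: int


@dataclass
class CertificateReport:
    status: str                                  # certified | saturated_bound | inconclusive
    witness: Optional[DualWitness] = None
    uncovered_blockers: List[str] = field(default_factory=list)
    kernel_dim: int = 0
    basis_rank: int = 0
    covered_kernel_dim: Optional[int] = None
    relax_config: Dict[str, object] = field(default_factory=dict)

    @property
    def complete(self) -> bool:
        return self.status in ("certified", "saturated_bound")


def relax_witness(
    model: StoichiometricModel,
    strict_set: Set[str],
    nonneg_set: Set[str],
    scheme: str = "motzkin",
    lam: float = 1.0,
    max_iter: int = 500_000,
    seed: int = 0,
):
    """Relaxation on the dual system: find v with (xi v)_m >= 1 for the strict
    rows and >= 0 for the non-negative rows (rows unit-normalized; the system
    is homogeneous, so a unit margin is w.l.o.g.).

    Iterates v <- v + lambda_t * xi_m0 on the least-satisfied row m0, with
    lambda_t constant ("minover") or proportional to the violation
    ("motzkin").  Returns a :class:`DualWitness` on success, else a
    :class:`StallReport` — exhaustion is a legitimate, inconclusive outcome.
    """
    if strict_set & nonneg_set:
        raise ValueError("strict and non-negative sets must be disjoint")
    if scheme not in ("minover", "motzkin"):
        raise ValueError(f"unknown relaxation scheme {scheme!r}")
    ridx = {r: j for j, r in enumerate(model.reaction_ids)}
    rows_map = model.rows()
    names: List[str] = []
    data: List[np.ndarray] = []
    targets: List[float] = []
    for m in model.metabolite_ids:
        if m in strict_set or m in nonneg_set:
            row = np.zeros(len(model.reaction_ids))
            for r, v in rows_map[m].items():
                row[ridx[r]] = float(v)
            nrm = np.linalg.norm(row)
            if nrm == 0.0:
                if m in strict_set:
                    # an all-zero row can never be strictly producible
                    return StallReport(blockers=[m], iterations=0)
                continue
            names.append(m)
            data.append(row / nrm)
            targets.append(1.0 if m in strict_set else 0.0)
    if not data:
        return DualWitness(v=np.zeros(len(model.reaction_ids)), margins={}, iterations=0)
    R = np.vstack(data)
    t = np.asarray(targets)
    strict_mask = t > 0.5
    rng = np.random.default_rng(seed)
    v0 = R.sum(axis=0) + 0.01 * rng.standard_normal(R.shape[1])
    margins = R @ v0
    gram = R @ R.T  # rows are unit vectors; row i0's update shifts margins by step*gram[i0]
    alpha = np.zeros(len(names))  # accumulated per-row step weights; v = v0 + R^T alpha
    for it in range(1, max_iter + 1):
        # the system is homogeneous: any state with all strict margins
        # positive and the non-negative rows satisfied rescales to a unit-
        # margin witness (greedy projection alone only reaches the margin
        # boundary asymptotically)
        if (not strict_mask.any() or margins[strict_mask].min() > 0.0) and (
            strict_mask.all() or margins[~strict_mask].min() >= 0.0
        ):
            v = v0 + R.T @ alpha
            margins = R @ v  # recompute directly: drops accumulated increment error
            ok_strict = not strict_mask.any() or margins[strict_mask].min() > 0.0
            ok_nonneg = strict_mask.all() or margins[~strict_mask].min() >= 0.0
            if ok_strict and ok_nonneg:
                scale = 1.0
                if strict_mask.any() and margins[strict_mask].min() < 1.0:
                    scale = 1.0 / margins[strict_mask].min()
                return DualWitness(
                    v=v * scale,
                    margins={m: float(x * scale) for m, x in zip(names, margins)},
                    iterations=it,
                )
            margins = R @ (v0 + R.T @ alpha)
        deficit = t - margins
        i0 = int(np.argmax(deficit))
        step = lam if scheme == "minover" else lam * max(deficit[i0], 0.0)
        alpha[i0] += step
        margins = margins + step * gram[i0]
    v = v0 + R.T @ alpha
    margins = R @ v
    deficit = t - margins
    order = np.argsort(-deficit)
    blockers = [names[i] for i in order[: min(10, len(names))] if deficit[i] > 0]
    return StallReport(blockers=blockers, iterations=max_iter)


def _strict_witness(
    model: StoichiometricModel,
    strict_set: Set[str],
    zero_set: Set[str],
    scheme: str = "motzkin",
    lam: float = 1.0,
    max_iter: int = 500_000,
    seed: int = 0,
):
    """Witness search for the certificate system: (xi v)_m = 0 exactly on the
    pool-covered rows, (xi v)_m > 0 on the uncovered candidate rows.

    The equality constraints are eliminated exactly: v is parametrized as
    v = P u with P a rational basis of the right null space of the covered
    rows, so the covered margins are zero by construction and the float
    relaxation only has to make the projected strict rows positive.  The
    system is homogeneous, so any u with all strict margins > 0 rescales to a
    unit-margin witness; candidate witnesses are re-verified in exact
    rational arithmetic before being accepted.  If a projected strict row
    vanishes identically, no witness can exist (that row's margin is forced
    to zero) and the row is reported as a blocker immediately.
    """
    from .kernel import nullspace_sparse

    N = len(model.reaction_ids)
    rows_map = model.rows()
    ridx = {r: j for j, r in enumerate(model.reaction_ids)}
    if not strict_set:
        return DualWitness(v=np.zeros(N), margins={}, iterations=0)
    eqs = []
    for m in zero_set:
        row = {ridx[r]: v for r, v in rows_map[m].items()}
        if row:
            eqs.append(row)
    P = nullspace_sparse(eqs, N) if eqs else [
        {j: Fraction(1)} for j in range(N)
    ]
    if not P:
        return StallReport(blockers=sorted(strict_set), iterations=0)
    names = sorted(strict_set)
    exact_rows: List[List[Fraction]] = []
    for m in names:
        row = {ridx[r]: v for r, v in rows_map[m].items()}
        proj = [
            sum((row.get(j, Fraction(0)) * x for j, x in basis_vec.items()), Fraction(0))
            for basis_vec in P
        ]
        if not any(proj):
            # margin forced to zero: Motzkin alternative, a pool through m exists
            return StallReport(blockers=[m], iterations=0)
        exact_rows.append(proj)
    R = np.array([[float(x) for x in row] for row in exact_rows])
    norms = np.linalg.norm(R, axis=1)
    Rn = R / norms[:, None]
    rng = np.random.default_rng(seed)
    u = Rn.sum(axis=0) + 0.01 * rng.standard_normal(Rn.shape[1])
    margins = Rn @ u
    gram = Rn @ Rn.T
    check_every = max(1, len(names))
    for it in range(1, max_iter + 1):
        deficit = 1.0 - margins
        i0 = int(np.argmax(deficit))
        if margins.min() > 0.0 and (deficit[i0] <= 0.0 or it % check_every == 0):
            # homogeneous system: rescale to unit margin and verify exactly
            scale = 1.0 / margins.min()
            u_exact = [Fraction(float(x) * scale) for x in u]
            exact_margins = [
                sum((c * ux for c, ux in zip(row, u_exact)), Fraction(0))
                for row in exact_rows
            ]
            if all(x > 0 for x in exact_margins):
                v = np.zeros(N)
                for j, basis_vec in enumerate(P):
                    uj = float(u_exact[j])
                    for col, x in basis_vec.items():
                        v[col] += uj * float(x)
                return DualWitness(
                    v=v,
                    margins={m: float(x) for m, x in zip(names, margins * scale)},
                    iterations=it,
                )
        step = lam if scheme == "minover" else lam * max(deficit[i0], 0.0)
        u = u + step * Rn[i0]
        margins = margins + step * gram[i0]
        if it % 1000 == 0:
            margins = Rn @ u  # drop accumulated increment error
    deficit = 1.0 - margins
    order = np.argsort(-deficit)
    blockers = [names[i] for i in order[: min(10, len(names))] if deficit[i] > 0]
    return StallReport(blockers=blockers or [names[int(order[0])]], iterations=max_iter)


def _exact_margin_check(
    model: StoichiometricModel,
    v: np.ndarray,
    strict_set: Set[str],
    nonneg_set: Set[str],
) -> bool:
    """Recompute xi v in rational arithmetic (floats are exact rationals) and
    check the declared inequalities: > 0 strict, >= 0 elsewhere."""
    vr = [Fraction(float(x)) for x in v]
    ridx = {r: j for j, r in enumerate(model.reaction_ids)}
    rows_map = model.rows()
    for m in strict_set | nonneg_set:
        s = sum((c * vr[ridx[r]] for r, c in rows_map[m].items()), Fraction(0))
        if m in strict_set:
            if s <= 0:
                return False
        elif s < 0:
            return False
    return True


def certify_completeness(
    model: StoichiometricModel,
    basis: PoolBasis,
    kern: KernelBasis,
    pooled: Optional[Set[str]] = None,
    scheme: str = "motzkin",
    lam: float = 1.0,
    max_iter: int = 500_000,
    seed: int = 0,
) -> CertificateReport:
    """Certify that ``basis`` spans every moiety conservation law of the model.

    * If |basis| equals the kernel dimension, the bound is saturated and no
      further independent pool can exist (status ``saturated_bound``).
    * Otherwise a relaxation witness is sought with strict rows = kernel-support
      candidates not covered by any pool (metabolites outside the kernel
      support are provably pool-free) and the covered rows held at margin
      zero, which any feasible direction satisfies automatically because each
      pool forces its members' margins to vanish.  A witness proves the
      uncovered candidates pool-free: for any pool k with support meeting the
      strict set, 0 = k^T xi v would be a sum of strictly positive and zero
      terms.  Certification additionally requires rank(basis) = dim of the
      kernel restricted to the pool-covered rows (status ``certified``).
      Anything else is ``inconclusive`` with the blocking rows listed.
    """
    pooled = set(basis.covered if pooled is None else pooled)
    cfg_echo = {"scheme": scheme, "lambda": lam, "max_iter": max_iter, "seed": seed}
    report = CertificateReport(
        status="inconclusive",
        kernel_dim=kern.dim,
        basis_rank=len(basis),
        relax_config=cfg_echo,
    )
    if len(basis) == kern.dim:
        report.status = "saturated_bound"
        return report
    candidates = candidate_metabolites(kern)
    uncovered = candidates - pooled
    if uncovered:
        res = _strict_witness(
            model, uncovered, pooled & candidates,
            scheme=scheme, lam=lam, max_iter=max_iter, seed=seed,
        )
        if isinstance(res, StallReport):
            report.uncovered_blockers = res.blockers
            return report
        report.witness = res
    ckd = covered_kernel_dim(model, pooled)
    report.covered_kernel_dim = ckd
    if len(basis) == ckd:
        report.status = "certified"
    else:
        logger.info("span gap: basis rank %d < covered-kernel dim %d", len(basis), ckd)
    return report


# ---------------------------------------------------------------------------
# Driver
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    """End-to-end search/certification settings.

    The first sweep over candidate pins uses ``first_sweep_restarts`` cheap
    annealing attempts per pin (most pools are small and found immediately);
    the certificate then directs full-budget, coefficient-escalated annealing
    at its blockers only, so metabolites that are provably pool-free never
    consume the full annealing budget.
    """

    anneal: AnnealConfig = field(default_factory=AnnealConfig)
    pruning: str = "kernel"          # kernel | mp | both
    mp_k_max: Optional[int] = None   # defaults to anneal.k_max
    relax_scheme: str = "motzkin"
    relax_lambda: float = 1.0
    relax_max_iter: int = 500_000
    max_rounds: int = 4
    first_sweep_restarts: int = 3
    seed: int = 0


def _candidate_components(
    model: StoichiometricModel, candidates: Set[str]
) -> List[List[str]]:
    """Connected components of candidates linked through shared reactions.

    Any pool solution is zero outside the candidate set, so each reaction
    constraint couples only the candidates it touches; solutions factorize
    over these components and each can be searched independently.
    """
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(candidates)
    for col in model.columns().values():
        touched = [m for m in col if m in candidates]
        for a, b in zip(touched, touched[1:]):
            g.add_edge(a, b)
    return [sorted(c) for c in nx.connected_components(g)]


def find_all_mcls(
    model: StoichiometricModel,
    config: Optional[PipelineConfig] = None,
) -> Tuple[PoolBasis, CertificateReport]:
    """The three-step pipeline: prune candidates, anneal out pools, certify.

    1. Exact left kernel -> candidate metabolites (optionally intersected
       with / unioned against belief-propagation marginals).
    2. For each uncovered candidate, pinned Metropolis annealing with k_max
       escalation, superposition reduction against the current basis, and
       exact-rank admission.
    3. Duality certificate; on an inconclusive outcome the blockers are
       re-pinned with escalated k_max and the search repeats, up to
       ``max_rounds`` outer rounds.  Deterministic given the seed.
    """
    cfg = config or PipelineConfig()
    kern = left_kernel(model)
    if kern.dim == 0:
        report = CertificateReport(status="certified", kernel_dim=0, basis_rank=0,
                                   covered_kernel_dim=0)
        return PoolBasis(), report

    candidates = candidate_metabolites(kern)
    if cfg.pruning in ("mp", "both"):
        from .mp_marginals import build_factor_graph, compute_marginals, prune_by_marginals

        graph = build_factor_graph(model, cfg.mp_k_max or cfg.anneal.k_max)
        table = compute_marginals(graph, seed=cfg.seed)
        if table.converged:
            mp_set = prune_by_marginals(table)
            if mp_set != candidates:
                logger.warning(
                    "BP candidate set (%d) disagrees with kernel support (%d); taking the union",
                    len(mp_set), len(candidates),
                )
            candidates = candidates | mp_set if cfg.pruning == "both" else (
                candidates | mp_set)
        else:
            logger.warning("BP did not converge; falling back to kernel-support pruning")

    components = _candidate_components(model, candidates)
    # the kernel splits exactly across components (they share no reaction),
    # so each component carries its own saturation bound
    comp_of: Dict[str, int] = {}
    for ci, comp in enumerate(components):
        for m in comp:
            comp_of[m] = ci
    local_dim = [covered_kernel_dim(model, set(comp)) for comp in components]
    assert sum(local_dim) == kern.dim  # the kernel factorizes over components
    local_rank = [0] * len(components)
    span = RationalSpan()
    basis = PoolBasis()
    pooled: Set[str] = set()          # metabolites known to sit in some pool
    failed: Set[str] = set()          # pins that exhausted every escalation

    def admit(pool: IntegerPool) -> None:
        pooled.update(pool.support)
        remainder = reduce_superposition(pool, basis)
        if remainder is None:
            return
        assert remainder.verify(model)
        pooled.update(remainder.support)
        vec = {m: Fraction(k) for m, k in remainder.coeffs}
        if span.add(vec):
            basis.pools.append(remainder)
            local_rank[comp_of[next(iter(remainder.support))]] += 1

    def run_pins(pins: Sequence[str], rnd: int, restarts: int, k_max: int,
                 skip_pooled: bool) -> None:
        for pin in pins:
            ci = comp_of[pin]
            if local_rank[ci] == local_dim[ci]:
                continue  # component saturated: no further independent pool
            if skip_pooled and pin in pooled:
                continue
            seed = (cfg.seed * 2654435761 + rnd * 1000003
                    + zlib.crc32(pin.encode()) % 65536) % (2**31)
            a = AnnealConfig(
                k_max=k_max, T0=cfg.anneal.T0, cooling=cfg.anneal.cooling,
                sweeps_per_T=cfg.anneal.sweeps_per_T, T_min=cfg.anneal.T_min,
                restarts=restarts, seed=seed, k_max_limit=cfg.anneal.k_max_limit,
                energy_form=cfg.anneal.energy_form, patience=cfg.anneal.patience,
            )
            pool = metropolis_anneal(model, pin, a, candidates=components[ci])
            if pool is None:
                failed.add(pin)
            else:
                failed.discard(pin)
                admit(pool)

    # first sweep: cheap attempts at every candidate pin; most pools are
    # small and surface immediately, and provably pool-free pins are left
    # for the certificate to witness instead of burning the full budget
    all_pins = [m for comp in components for m in comp]
    run_pins(all_pins, 0, min(cfg.first_sweep_restarts, cfg.anneal.restarts),
             cfg.anneal.k_max, skip_pooled=True)

    report = CertificateReport(status="inconclusive", kernel_dim=kern.dim)
    for rnd in range(cfg.max_rounds):
        size_before = len(basis)
        report = certify_completeness(
            model, basis, kern, pooled=pooled,
            scheme=cfg.relax_scheme, lam=cfg.relax_lambda,
            max_iter=cfg.relax_max_iter, seed=cfg.seed + rnd,
        )
        report.basis_rank = len(basis)
        if report.complete:
            break
        if rnd == cfg.max_rounds - 1:
            break
        # escalate the coefficient cap for relaxation blockers; re-pin gap
        # components (local rank below local kernel dim) with fresh seeds
        k_max = min(cfg.anneal.k_max * (2**rnd), cfg.anneal.k_max_limit)
        if report.uncovered_blockers:
            run_pins(report.uncovered_blockers, rnd + 1, cfg.anneal.restarts,
                     k_max, skip_pooled=False)
        gap_pins = [
            m for ci, comp in enumerate(components)
            if local_rank[ci] < local_dim[ci] for m in comp
        ]
        run_pins(gap_pins, cfg.max_rounds + rnd + 1,
                 min(cfg.first_sweep_restarts, cfg.anneal.restarts),
                 cfg.anneal.k_max, skip_pooled=False)
        if len(basis) == size_before and not report.uncovered_blockers and rnd > 0:
            break  # a fresh-seed gap round added nothing; repetition is futile
    _minimize_representatives(basis, model)
    return basis, report


def _minimize_representatives(basis: PoolBasis, model: StoichiometricModel) -> None:
    """Mutually reduce basis pools so no representative contains an integer
    multiple of another (a superposition discovered before its parts would
    otherwise survive).  Replacing p by p - t*q preserves the span, the
    non-negativity and linear independence, so only the representatives
    change; the total coefficient mass strictly decreases, so this
    terminates."""
    changed = True
    while changed:
        changed = False
        for i, p in enumerate(basis.pools):
            others = PoolBasis(pools=basis.pools[:i] + basis.pools[i + 1:])
            r = reduce_superposition(p, others)
            assert r is not None  # an independent pool cannot vanish
            if r != p:
                assert r.verify(model)
                basis.pools[i] = r
                changed = True
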