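"""Random sparse reaction-network ensemble: generator, analytic pool counts,
scaling experiment, planted-pool fixtures, and the brute-force oracle.

The ensemble draws each stoichiometric coefficient independently as +1 with
probability c/(2N), -1 with probability c/(2N) and 0 otherwise.  In the large
sparse limit (N/M fixed) this produces Poisson in/out degrees with mean c per
metabolite and cM/N per reaction — a caricature of a metabolic network once
its heavy-tailed hub compounds (water, ATP, ...) are removed.

For this ensemble the expected number of size-L conserved pools with unit
coefficients has a closed form.  A fixed set of L rows forms a pool iff every
one of the N columns sums to zero on those rows; with p = c/(2N) the
per-column probability is the trinomial mass

    q(L) = sum_a  L! / (a! a! (L-2a)!) * p^(2a) * (1-2p)^(L-2a)

(a = number of +1/-1 pairs), giving  <N_L> = C(M,L) * q(L)^N.  For L = 2,
q(2) = (1-c/N)^2 + 2 (c/(2N))^2.  <N_L> counts superpositions of smaller
pools too; the independent count subtracts them.  For L = 2 the only
superpositions are pairs of all-zero rows (two size-1 "pools"), whence

    <N_2^indep> = C(M,2) * ( q(2)^N - q(1)^(2N) ).

Lemma (unit coefficients suffice for L = 2): with entries in {-1, 0, +1}, a
size-2 pool (k_a, k_b) needs k_a x_ar + k_b x_br = 0 for every column; any
column where exactly one entry is nonzero is unbalanced, and a column with
both nonzero forces k_a = ±k_b, so non-negativity and gcd-canonicality force
k_a = k_b = 1.

Summing <N_L> over L >= 2 gives a total pool count proportional to M at fixed
c and N/M, which is the analytic root of the observed linear scaling of the
pool-basis size with network size.

An all-zero metabolite row is a degenerate size-1 "pool"; the expectation
formulas above include such rows, so the generator's reports flag them and
the pipeline counts only pools of size >= 2 (zero rows are filtered).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from fractions import Fraction
from math import comb, factorial
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np

from .kernel import candidate_metabolites, left_kernel
from .mc_search import IntegerPool, PoolBasis, RationalSpan
from .model_io import StoichiometricModel

__all__ = [
    "RandomEnsembleParams",
    "PoolCountEstimate",
    "BruteForceResult",
    "ScalingResult",
    "generate_random_network",
    "enumerate_mcls_bruteforce",
    "count_size2_pools",
    "expected_pool_count",
    "scaling_experiment",
    "plant_pools",
]

logger = logging.getLogger(__name__)


@dataclass
class RandomEnsembleParams:
    """M metabolites, N reactions, mean metabolite degree c, seed."""

    M: int
    N: int
    c: float
    seed: int = 0

    def __post_init__(self) -> None:
        if self.M < 1 or self.N < 1:
            raise ValueError("M and N must be >= 1")
        if not (0 <= self.c <= self.N):
            raise ValueError("need 0 <= c <= N (entry probability c/(2N) <= 1/2)")


def generate_random_network(params: RandomEnsembleParams) -> StoichiometricModel:
    """Draw a model from the ensemble; identical seed -> identical matrix."""
    rng = np.random.default_rng(params.seed)
    p = params.c / (2 * params.N)
    u = rng.random((params.M, params.N))
    mat = np.zeros((params.M, params.N), dtype=np.int8)
    mat[u < p] = 1
    mat[(u >= p) & (u < 2 * p)] = -1
    mets = [f"m{i:04d}" for i in range(params.M)]
    rxns = [f"r{j:04d}" for j in range(params.N)]
    coeff: Dict[Tuple[str, str], Fraction] = {}
    rows_idx, cols_idx = np.nonzero(mat)
    for i, j in zip(rows_idx.tolist(), cols_idx.tolist()):
        coeff[(mets[i], rxns[j])] = Fraction(int(mat[i, j]))
    return StoichiometricModel(
        metabolite_ids=mets,
        reaction_ids=rxns,
        coeff=coeff,
        exchange_ids=set(),
        provenance=f"random-ensemble:M={params.M},N={params.N},c={params.c},seed={params.seed}",
    )


# ---------------------------------------------------------------------------
# Brute-force oracle
# ---------------------------------------------------------------------------


@dataclass
class BruteForceResult:
    """Ground truth from exhaustive enumeration."""

    basis: PoolBasis                 # canonical independent basis (size, then lexicographic)
    n_solutions: int                 # count of all non-zero solutions (pre-canonicalization)
    pools: List[IntegerPool]         # all distinct canonical pools
    coverage: Set[str] = field(default_factory=set)


def enumerate_mcls_bruteforce(
    model: StoichiometricModel, k_max: int, max_candidates: int = 20
) -> BruteForceResult:
    """Exhaustively scan all k-vectors over the kernel-support candidates.

    The search space is (k_max+1)^|candidates|, so the candidate count is
    guarded.  This routine is the ground-truth oracle for every stochastic
    component of the package; it must stay independent of the annealing code.
    """
    kern = left_kernel(model)
    cands = sorted(candidate_metabolites(kern))
    if len(cands) > max_candidates:
        raise ValueError(
            f"{len(cands)} candidate metabolites exceeds the brute-force guard "
            f"({max_candidates}); search space (k_max+1)^n is infeasible"
        )
    if not model.is_integer():
        raise ValueError("brute force requires an integer matrix; run clear_denominators")
    rows = model.rows()
    rxns = sorted({r for m in cands for r in rows[m]})
    ridx = {r: j for j, r in enumerate(rxns)}
    A = np.zeros((len(cands), len(rxns)), dtype=np.int64)
    for i, m in enumerate(cands):
        for r, v in rows[m].items():
            A[i, ridx[r]] = int(v)

    n = len(cands)
    base = k_max + 1
    total = base**n
    n_solutions = 0
    canon: Dict[Tuple[Tuple[str, int], ...], IntegerPool] = {}
    block = 1 << 14
    powers = base ** np.arange(n)
    for start in range(0, total, block):
        idx = np.arange(start, min(start + block, total))
        K = (idx[:, None] // powers[None, :]) % base  # rows = k-vectors
        resid = K @ A
        sol_mask = np.all(resid == 0, axis=1) & np.any(K > 0, axis=1)
        for krow in K[sol_mask]:
            n_solutions += 1
            pool = IntegerPool.from_dict(
                {cands[i]: int(krow[i]) for i in range(n) if krow[i]}
            )
            canon.setdefault(pool.coeffs, pool)

    pools = sorted(canon.values(), key=lambda p: (p.size, p.coeffs))
    span = RationalSpan()
    basis = PoolBasis()
    for p in pools:
        if span.add({m: Fraction(k) for m, k in p.coeffs}):
            basis.pools.append(p)
    coverage = set()
    for p in pools:
        coverage.update(p.support)
    return BruteForceResult(basis=basis, n_solutions=n_solutions, pools=pools, coverage=coverage)


def count_size2_pools(model: StoichiometricModel) -> int:
    """Count independent size-2 unit pools by direct pair scan: unordered row
    pairs (a, b), both nonzero, with row_a + row_b = 0.  O(M N), no guard."""
    mets = model.metabolite_ids
    ridx = {r: j for j, r in enumerate(model.reaction_ids)}
    mat = np.zeros((len(mets), len(model.reaction_ids)), dtype=np.int64)
    midx = {m: i for i, m in enumerate(mets)}
    for (m, r), v in model.coeff.items():
        mat[midx[m], ridx[r]] = int(v)
    nonzero = mat[np.any(mat != 0, axis=1)]
    counts: Dict[bytes, int] = {}
    for row in nonzero:
        counts[row.tobytes()] = counts.get(row.tobytes(), 0) + 1
    pairs = 0
    for row in nonzero:
        pairs += counts.get((-row).tobytes(), 0)
    return pairs // 2


# ---------------------------------------------------------------------------
# Analytic expectations
# ---------------------------------------------------------------------------


@dataclass
class PoolCountEstimate:
    L: int
    expected_total: float
    expected_independent: float
    mc_mean: Optional[float] = None
    mc_ci: Optional[Tuple[float, float]] = None
    mc_replicates: int = 0


def _q(L: int, p: Fraction) -> Fraction:
    """Probability that L iid {+1 (p), -1 (p), 0} entries sum to zero."""
    total = Fraction(0)
    for a in range(L // 2 + 1):
        ways = factorial(L) // (factorial(a) * factorial(a) * factorial(L - 2 * a))
        total += ways * p ** (2 * a) * (1 - 2 * p) ** (L - 2 * a)
    return total


def expected_pool_count(
    params: RandomEnsembleParams,
    L: int,
    k_max: int = 3,
    mc_replicates: int = 0,
) -> PoolCountEstimate:
    """Analytic expected number of size-L unit-coefficient pools, with the
    independent-pool correction, optionally cross-checked by Monte Carlo.

    The L=2 correction (subtracting pairs of all-zero rows) is exact in
    expectation; for L>=3 superpositions into two disjoint sub-pools are
    subtracted (higher-order splits are neglected).  Monte Carlo counts use
    the direct pair scan for L=2 and the brute-force oracle otherwise.
    """
    if L < 1:
        raise ValueError("L must be >= 1")
    p = Fraction(params.c).limit_denominator(10**9) / (2 * params.N)
    M, N = params.M, params.N
    qL = float(_q(L, p))
    total = comb(M, L) * qL**N
    if L == 1:
        indep = total  # all-zero rows; degenerate, flagged by callers
    elif L == 2:
        indep = comb(M, 2) * (qL**N - float(_q(1, p)) ** (2 * N))
    else:
        overcount = 0.0
        for l in range(1, L):
            overcount += comb(L, l) * float(_q(l, p)) ** N * float(_q(L - l, p)) ** N
        indep = total - comb(M, L) * overcount / 2.0
    est = PoolCountEstimate(L=L, expected_total=total, expected_independent=indep)
    if mc_replicates > 0:
        vals = []
        for rep in range(mc_replicates):
            mdl = generate_random_network(
                RandomEnsembleParams(M, N, params.c, seed=(params.seed * 9973 + rep) % 2**31)
            )
            if L == 2:
                vals.append(count_size2_pools(mdl))
            else:
                res = enumerate_mcls_bruteforce(mdl, k_max)
                vals.append(sum(1 for q in res.pools if q.size == L))
        from scipy.stats import chi2

        # pool occurrences are sums of rare, nearly independent indicators,
        # so the replicate total is close to Poisson; use the exact Garwood
        # interval on the total rather than a normal approximation, which
        # misbehaves at the small means typical of this ensemble
        total_count = int(sum(vals))
        R = len(vals)
        lo = 0.0 if total_count == 0 else float(chi2.ppf(0.025, 2 * total_count)) / 2
        hi = float(chi2.ppf(0.975, 2 * (total_count + 1))) / 2
        est.mc_mean = total_count / R
        est.mc_ci = (lo / R, hi / R)
        est.mc_replicates = mc_replicates
    return est


# ---------------------------------------------------------------------------
# Scaling experiment
# ---------------------------------------------------------------------------


@dataclass
class ScalingResult:
    rows: List[Tuple[int, float]]    # (M, mean basis size)
    slope: float                     # least squares through the origin
    r_squared: float


def scaling_experiment(
    c: float,
    ratio: float,
    M_list: Sequence[int],
    replicates: int,
    seed: int = 0,
    config=None,
) -> ScalingResult:
    """Mean pool-basis size vs network size over the ensemble.

    Runs the full search/certification pipeline per replicate (never the
    brute-force oracle), fits basis_size = slope * M through the origin and
    reports the fit quality.

    The default per-replicate pipeline settings start the annealer cold
    (T0 = 0.5): the pools of this sparse ensemble are small, so a quench
    from a near-empty state finds them far more reliably than a hot start
    that first has to anneal away bulk disorder in the large connected
    candidate component.
    """
    from .dual_certificate import PipelineConfig, find_all_mcls
    from .mc_search import AnnealConfig

    rows: List[Tuple[int, float]] = []
    for M in M_list:
        N = max(1, round(ratio * M))
        sizes = []
        for rep in range(replicates):
            s = (seed * 7919 + M * 104729 + rep) % 2**31
            cfg = config or PipelineConfig(
                seed=s,
                max_rounds=2,
                relax_max_iter=150_000,
                first_sweep_restarts=3,
                anneal=AnnealConfig(T0=0.5, restarts=10, patience=20),
            )
            mdl = generate_random_network(RandomEnsembleParams(M, N, c, seed=s))
            basis, _ = find_all_mcls(mdl, cfg)
            sizes.append(len(basis))
        rows.append((M, float(np.mean(sizes))))
    x = np.asarray([m for m, _ in rows], dtype=float)
    y = np.asarray([s for _, s in rows], dtype=float)
    slope = float((x @ y) / (x @ x))
    ss_res = float(np.sum((y - slope * x) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return ScalingResult(rows=rows, slope=slope, r_squared=r2)


# ---------------------------------------------------------------------------
# Planted-pool fixtures
# ---------------------------------------------------------------------------


def plant_pools(
    M: int,
    N: int,
    pool_specs: Sequence[Dict[str, int]],
    c: float = 1.0,
    seed: int = 0,
) -> Tuple[StoichiometricModel, PoolBasis]:
    """Build a network whose left kernel is exactly the span of the planted
    coefficient vectors, plus a producible random background.

    ``pool_specs`` are coefficient maps (metabolite id -> positive integer);
    supports may overlap (selenium-style shared species).  Reactions within
    the planted block form an integer basis of the orthogonal complement of
    the planted vectors, so the block's left kernel is exactly their span.
    Every background metabolite receives an exchange column, which forces its
    coefficient to zero in any conservation law; background reactions with
    ±1 entries at density c/(2 N_bg) add realistic clutter without touching
    the planted kernel.

    Returns the model and the ground-truth basis, in spec order.
    """
    from .kernel import nullspace_sparse

    planted = []
    for spec in pool_specs:
        pool = IntegerPool.from_dict(spec)
        if pool.coeffs_dict != {m: int(k) for m, k in spec.items() if k}:
            raise ValueError(f"pool spec not gcd-canonical: {spec}")
        planted.append(pool)
    support = sorted({m for p in planted for m in p.support})
    sidx = {m: i for i, m in enumerate(support)}
    if len(pool_specs) == 0:
        raise ValueError("need at least one pool spec")
    # rows = planted vectors as equations over the support
    eqs = [
        {sidx[m]: Fraction(k) for m, k in p.coeffs}
        for p in planted
    ]
    ortho = nullspace_sparse(eqs, len(support))
    # sanity: planted vectors must be independent, else kernel dim mismatches
    span = RationalSpan()
    for p in planted:
        if not span.add({m: Fraction(k) for m, k in p.coeffs}):
            raise ValueError("planted pools are linearly dependent")
    if len(ortho) != len(support) - len(planted):
        raise ValueError("inconsistent planted-pool specification")

    n_bg = M - len(support)
    if n_bg < 0:
        raise ValueError("M smaller than the planted support")
    bg_mets = [f"bg{i:04d}" for i in range(n_bg)]
    mets = support + bg_mets
    coeff: Dict[Tuple[str, str], Fraction] = {}
    rxns: List[str] = []

    from math import lcm

    for j, col in enumerate(ortho):
        rid = f"plant_r{j:03d}"
        rxns.append(rid)
        mult = lcm(*(v.denominator for v in col.values())) if col else 1
        for i, v in col.items():
            coeff[(support[i], rid)] = v * mult

    exch = set()
    for i, m in enumerate(bg_mets):
        rid = f"EX_{m}"
        rxns.append(rid)
        exch.add(rid)
        coeff[(m, rid)] = Fraction(1)

    n_bg_rxn = max(0, N - len(rxns))
    rng = np.random.default_rng(seed)
    p_entry = min(0.5, c / (2 * max(1, n_bg_rxn))) if n_bg_rxn else 0.0
    for j in range(n_bg_rxn):
        rid = f"bg_r{j:04d}"
        rxns.append(rid)
        if n_bg == 0:
            continue
        u = rng.random(n_bg)
        for i in np.nonzero(u < 2 * p_entry)[0].tolist():
            coeff[(bg_mets[i], rid)] = Fraction(1 if u[i] < p_entry else -1)

    model = StoichiometricModel(
        metabolite_ids=mets,
        reaction_ids=rxns,
        coeff=coeff,
        exchange_ids=exch,
        provenance=f"planted:{len(planted)} pools,seed={seed}",
    )
    truth = PoolBasis(pools=planted)
    # construction invariant: kernel dim equals the number of planted pools
    kern = left_kernel(model)
    if kern.dim != len(planted):
        raise AssertionError("planted construction produced extra kernel directions")
    return model, truth
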