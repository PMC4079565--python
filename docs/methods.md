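# Methods

## Model and problem statement

A stoichiometric network is an M×N rational matrix ξ (metabolites ×
reactions, exchange columns included, substrates negative, products
positive). A *moiety conservation law* (MCL, "conserved pool") is a
non-negative integer vector k ≠ 0 with kᵀξ = 0, taken gcd-canonical (the
coefficients on the support are coprime). The package computes a maximal
linearly independent set of MCLs together with a certificate that no further
independent MCL exists. Semi-positive conservation laws — non-negative real
combinations — are generated by such a basis, and the left-kernel dimension
dim{w : wᵀξ = 0} is an upper bound on the number of independent ones.

Reversibility never enters: the defining constraint uses only ξ, so closing
a growth medium removes whole exchange *columns*, and a medium is a set of
exchange reactions to keep. Exchange columns are detected as columns with a
single nonzero entry (plus SBML boundary-condition species, honored by
dropping the external row).

## Exactness policy

Whether kᵀξ = 0 holds is a yes/no question, and genome-scale reconstructions
mix unit coefficients with entries like 1/50; float arithmetic can
manufacture or destroy kernel vectors. All structural computations —
parsing, kernel, rank tests, pool verification, the final certificate
margins — run over `fractions.Fraction`. Decimal strings are parsed directly
to rationals (`"0.02"` → 1/50) and never round-trip through a float; for the
same reason the SBML reader parses stoichiometry attribute strings at the
XML level rather than through a numeric model API. `clear_denominators`
multiplies each column by the LCM of its denominators — a positive
per-column scaling that provably leaves the MCL solution set unchanged — so
the search operates on integer matrices.

All-zero metabolite rows (species in no reaction) are trivially "conserved"
singletons; they are excluded from the kernel and reported separately, and
every pool count in this package refers to pools of size ≥ 2 on active rows.

## Step 1 — pruning

The left kernel is computed by sparse Gaussian elimination over ℚ with
scaled partial pivoting (pivot maximizes |entry|/row-max; ties broken by
lowest column index, equations processed in input order — fully
deterministic). Every emitted vector is re-verified against every column. A
second elimination with a deliberately different pivot rule serves as an
independent cross-check in the tests, as does sympy's nullspace.

Any MCL lies in the kernel span and therefore vanishes off the union of
kernel supports; that union is the candidate set. Candidates are then split
into connected components of the candidate–reaction graph. Because two
components share no reaction, every kernel vector (hence every pool) lives
inside a single component, the kernel dimension is the sum of per-component
dimensions (asserted at run time), and the search runs per component.

Optionally (`pruning="mp"` / `"both"`), per-metabolite marginals of the
uniform distribution over the solution space {k ∈ {0..k_max}ᴹ : kᵀξ = 0} are
estimated by damped sum-product message passing on the factor graph whose
variables are metabolites and whose factors are the per-reaction balance
constraints. Factor messages are computed by convolution over the bounded
partial sum Σξk. The all-zero solution is part of the measure, so marginals
never degenerate and pool membership is read from p_m(0) < 1. Sum-product is
exact on trees (tested against enumeration) and can under-count on loops, so
the driver takes the union with the kernel candidate set and logs
disagreements. Defaults: k_max = 4, damping 0.5, tolerance 1e-8, ≤ 10⁴
iterations. Kernel pruning is the default; both prunings produce identical
candidate lists on every network we generate, but the kernel route needs no
convergence argument.

## Step 2 — annealing search

Solutions of kᵀξ = 0 are the ground states of E(k) = Σᵣ(Σₘ ξₘᵣ kₘ)², a
non-negative integer on integer matrices (an absolute-value variant is
available behind `energy_form="abs"`; any form with E = 0 ⇔ feasibility is
equivalent). A Metropolis chain proposes single-coordinate ±1 moves
restricted to the candidate component, accepting with min(1, e^(−ΔE/T)), and
T follows a geometric schedule. The all-zero state is excluded by *pinning*:
each run fixes one target metabolite at k ≥ 1, which simultaneously
guarantees coverage of every candidate and biases the chain toward small
pools containing the pin. The first E = 0 state visited is returned,
gcd-canonicalized and verified exactly.

Defaults: k_max 4 (escalated ×2 up to 64 for certificate blockers, since a
column integerized from 1/50-stoichiometry forces coefficients ~50), T₀ 2.0,
cooling 0.95, 10·|candidates| proposals per temperature level, T_min 1e-3,
20 restarts, and a patience rule that abandons a restart after 25
temperature levels without improvement of the best energy (a frozen chain
does not unfreeze by further cooling). Detailed balance of the chain at
fixed T is unit-tested against the closed-form Boltzmann distribution on a
two-variable system.

Superpositions of pools are themselves ground states; a found state is
reduced by repeatedly subtracting the largest multiple of each known basis
pool that keeps all coefficients non-negative (each remainder is again a
solution, by linearity). Admission to the basis is by exact incremental
rank; the basis can never exceed the kernel dimension. After the driver
finishes, representatives are mutually reduced once more so that no basis
pool contains an integer multiple of another — discovery order otherwise
lets a superposition that surfaced early survive as a representative.

### Driver scheduling

The driver first sweeps every candidate pin with a small restart budget
(default 3): real pools are overwhelmingly small and surface immediately,
while pins that belong to no pool would otherwise burn the full budget
pointlessly — the certificate, not the annealer, is the right tool to
dispose of them. Certification then drives the expensive work: relaxation
blockers are re-annealed with full restarts and doubled k_max each round,
and components whose admitted-pool rank is below their local kernel
dimension get one fresh-seed re-sweep per round. The loop stops on a
complete certificate, after `max_rounds` (default 4), or when a round
changes nothing. All randomness derives from one seed (per-pin seeds mix
the round index and a CRC of the metabolite id), so runs are reproducible
bit-for-bit.

## Step 3 — the completeness certificate

Producibility and conservation are dual (Motzkin's transposition theorem):
for a row subset R, either some v satisfies ξv ≥ 0 with strict inequalities
on R, or an MCL has positive weight on R. The certificate seeks such a
witness for R = candidates not covered by any discovered pool.

Covered rows are special: any feasible v gives them margin exactly zero
(inside a pool, non-negative margins summing to zero via kᵀξv = 0). Exact
zero is unreachable by float iteration, so the implementation eliminates
those rows analytically — v = Pu with P an exact rational basis of the right
null space of the covered rows — and relaxes only the projected strict rows.
If a projected strict row vanishes identically, its margin is forced to zero
and no witness exists; this detects most genuine infeasibilities at
iteration zero. The system is homogeneous, so any u with all strict margins
positive rescales to a unit-margin witness; candidate witnesses are
re-verified in exact rational arithmetic (the float u is converted exactly;
covered margins are zero by construction of P). The general-purpose
`relax_witness` (strict + non-negative targets, MinOver constant step or
Motzkin violation-proportional step, least-satisfied row first) uses the
same rescaling rule — pure greedy projection only reaches the margin
boundary asymptotically. Defaults: Motzkin scheme, λ = 1, 5·10⁵ row updates.

A converged witness alone does not certify completeness: an undiscovered
pool supported entirely *inside* the covered set would slip through (a
one-column network with balance A − B + C − D = 0 realizes this: two
disjoint pairs cover all four species while the kernel has dimension three).
Certification therefore requires, in addition, rank(basis) = dim of the left
kernel of the covered row-submatrix, computed exactly. When the bound
|basis| = kernel dim is reached the certificate is immediate
(`saturated_bound`). Everything else is `inconclusive`, with the
least-satisfied rows reported as blockers; non-convergence proves nothing
and is never upgraded. This rank condition is deliberately conservative: a
mixed-sign kernel vector confined to the covered rows keeps the status
`inconclusive` even when the pool basis is in fact complete.

## Random-ensemble theory

The generator draws each entry independently: +1 with probability c/(2N),
−1 with probability c/(2N), 0 otherwise, giving Poisson degrees with mean c
per metabolite and cM/N per reaction — a caricature of a metabolic network
after its hub compounds are removed. For unit-coefficient pools on a fixed
set of L rows, a column is balanced with probability
q(L) = Σₐ L!/(a!a!(L−2a)!) p²ᵃ(1−2p)^(L−2a) (a = number of +/− pairs), so
⟨N_L⟩ = C(M,L)·q(L)ᴺ. With entries in {−1,0,+1}, a size-2 pool forces equal
unit coefficients (any column touching one member must touch the other with
opposite sign), and the only size-2 superpositions are pairs of all-zero
rows, giving the exact independent count ⟨N₂ⁱⁿᵈ⟩ = C(M,2)(q(2)ᴺ − q(1)²ᴺ);
for L ≥ 3 the correction subtracts two-part splits and is approximate.
Summing over L shows ⟨total pools⟩ ∝ M at fixed c and N/M — the analytic
root of the linear basis-size scaling.

Monte-Carlo cross-checks count size-2 pools by direct row-pair scan
(row_a = −row_b, both nonzero; O(MN), no enumeration guard) and compare with
the analytic value using an exact Poisson (Garwood) interval on the summed
count across replicates — pool occurrences are sums of rare, weakly
dependent indicators, for which the normal-approximation interval
misbehaves at small means.

The scaling experiment runs the full pipeline (never the brute-force oracle)
on 20 replicates per size, M ∈ {50, 100, 200, 400}, N = M, c = 2, and fits
the mean basis size through the origin. Its per-replicate pipeline settings
start the annealer cold (T₀ = 0.5, 10 restarts, 2 rounds, relaxation budget
1.5·10⁵): the pools of this ensemble are small, and a quench from the
near-empty state finds them far more reliably than a hot start that must
first anneal away bulk disorder in the percolating candidate component.
These sizes and budgets are the experiment's own design and are asserted to
give R² ≥ 0.9 in the acceptance suite.

### Planted-pool fixtures

`plant_pools` builds ground-truth instances: the reactions on the planted
support form an integer basis of the orthogonal complement of the planted
coefficient vectors (computed by the same exact nullspace routine), so the
left kernel restricted to that block is exactly the planted span; every
background metabolite receives an exchange column, which forces its
coefficient to zero in any conservation law, plus ±1 background clutter.
Overlapping supports (shared species) are allowed. The construction is
verified at build time (kernel dimension must equal the number of planted
pools).

### Brute-force oracle

`enumerate_mcls_bruteforce` exhaustively scans {0..k_max}^candidates
(guarded at 20 candidates), returning all canonical solutions, a
size-then-lexicographic greedy independent basis, and the raw solution
count. It is the ground truth for every stochastic test and shares no code
with the annealing path.

## What the synthetic data does and does not show

The ensemble and the planted fixtures reproduce the features the method
actually exploits — sparsity, small overlapping pools, exchange columns,
non-unit and rational coefficients (via planted specs and fixture models) —
but not the heavy-tailed degree distribution of real metabolism
(water/ATP-like hubs), compartment structure, or correlated reaction
chemistry. Passing tests therefore demonstrate correctness of the
algorithms and calibration of the ensemble theory, not biological coverage;
the genome-scale behaviour (e.g. tRNA pairs, the 53-species ACP pool under
a rich medium, extra metal-ion pools under a minimal medium) is exercised
through `examples/reproduce_published.py` on reconstructions the user
supplies.

## Numerical choices and degenerate inputs

* Ties in annealing proposals and pin order are fixed by sorted metabolite
  ids; all stochastic stages consume explicit seeds derived from one global
  seed by fixed offsets.
* Pool reports print `(k)` prefixes only for k > 1; round-trip readers are
  provided.
* Degenerate inputs: empty kernel → immediate certified empty basis;
  metabolites in no reaction → reported as trivial singletons; an all-zero
  strict row in a witness system → immediate stall (it can never be
  strictly producible); k_max < 1, inconsistent media, non-canonical or
  dependent planted specs → errors.
* `relax_witness` margins are reported on unit-normalized rows; the
  homogeneous rescaling makes the unit-margin target a convention, not a
  tolerance.

## Known limitations

* The certificate's rank condition is conservative (see above): a complete
  basis can remain `inconclusive` when mixed-sign kernel vectors hide inside
  the covered set. No false `certified`/`saturated_bound` is possible.
* Annealing offers no finite-time guarantee; pools with very large
  coefficients (beyond the k_max escalation limit 64) would be missed and
  surface as persistent blockers.
* The analytic independent-pool correction is exact only for L ≤ 2.
* Belief propagation may fail to converge on dense loopy instances; the
  driver then falls back to kernel pruning (logged).
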