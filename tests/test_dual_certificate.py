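"""Producibility-duality witnesses, completeness certification, the driver."""

from __future__ import annotations

import pytest

from moietypools.dual_certificate import (
    DualWitness,
    PipelineConfig,
    StallReport,
    certify_completeness,
    find_all_mcls,
    relax_witness,
)
from moietypools.fixtures import (
    closed_two_cycle,
    open_chain,
    toy_enzyme_network,
    triangle_pools,
)
from moietypools.kernel import left_kernel
from moietypools.mc_search import IntegerPool, PoolBasis
from moietypools.model_io import apply_medium, MediumSpec
from moietypools.random_ensemble import (
    RandomEnsembleParams,
    enumerate_mcls_bruteforce,
    generate_random_network,
    plant_pools,
)

from conftest import coverage_of, same_span


class TestRelaxWitness:
    def test_open_chain_everything_producible(self):
        model = open_chain()
        res = relax_witness(model, {"A", "B"}, set(), seed=0)
        assert isinstance(res, DualWitness)
        assert all(m >= 1.0 - 1e-9 for m in res.margins.values())

    def test_closed_cycle_stalls_by_the_alternative(self):
        # {A,B} is a pool, so no flux direction can make A strictly
        # producible while B stays non-negative: the relaxation must stall
        model = closed_two_cycle()
        res = relax_witness(model, {"A"}, {"B"}, max_iter=20_000, seed=0)
        assert isinstance(res, StallReport)
        assert "A" in res.blockers or "B" in res.blockers

    def test_invalid_inputs(self):
        model = open_chain()
        with pytest.raises(ValueError):
            relax_witness(model, {"A"}, {"A"})
        with pytest.raises(ValueError):
            relax_witness(model, {"A"}, set(), scheme="fastest")

    @pytest.mark.parametrize("scheme,lam", [("motzkin", 1.0), ("minover", 0.1)])
    def test_both_schemes_converge_on_feasible_system(self, scheme, lam):
        res = relax_witness(open_chain(), {"A", "B"}, set(), scheme=scheme, lam=lam)
        assert isinstance(res, DualWitness)

    def test_witness_margins_hold_in_exact_arithmetic(self):
        """A returned witness must satisfy the inequalities when the margins
        are recomputed in rational arithmetic from the float vector."""
        from moietypools.dual_certificate import _exact_margin_check

        model = open_chain()
        res = relax_witness(model, {"A", "B"}, set(), seed=0)
        assert _exact_margin_check(model, res.v, {"A", "B"}, set())


class TestCertify:
    def test_saturated_bound_short_circuits(self):
        model = toy_enzyme_network()
        kern = left_kernel(model)
        basis = PoolBasis(pools=[
            IntegerPool.from_dict({"E": 1, "ES": 1}),
            IntegerPool.from_dict({"S": 1, "ES": 1, "P": 1}),
        ])
        report = certify_completeness(model, basis, kern)
        assert report.status == "saturated_bound"

    def test_empty_basis_on_open_network_certifies(self):
        # kernel dim 0: nothing to find, completeness is immediate
        model = open_chain()
        kern = left_kernel(model)
        report = certify_completeness(model, PoolBasis(), kern)
        assert report.complete

    def test_incomplete_basis_is_not_certified(self):
        # triangle fixture: two disjoint pairs cover everything but the
        # kernel dim is 3 -> certification must refuse
        model = triangle_pools()
        kern = left_kernel(model)
        basis = PoolBasis(pools=[
            IntegerPool.from_dict({"A": 1, "B": 1}),
            IntegerPool.from_dict({"C": 1, "D": 1}),
        ])
        report = certify_completeness(model, basis, kern)
        assert report.status == "inconclusive"
        assert report.covered_kernel_dim == 3

    def test_partial_coverage_with_remaining_pool_stalls(self):
        model = closed_two_cycle()
        kern = left_kernel(model)
        report = certify_completeness(model, PoolBasis(), kern, max_iter=20_000)
        assert report.status == "inconclusive"
        assert report.uncovered_blockers


class TestDriver:
    def test_toy_network_full_pipeline(self):
        model = toy_enzyme_network()
        basis, cert = find_all_mcls(model, PipelineConfig(seed=0))
        assert cert.status == "saturated_bound"
        found = sorted((p.coeffs for p in basis))
        expected = sorted([
            IntegerPool.from_dict({"E": 1, "ES": 1}).coeffs,
            IntegerPool.from_dict({"S": 1, "ES": 1, "P": 1}).coeffs,
        ])
        assert found == expected

    def test_closed_cycle_pool_found_despite_stalled_relaxation(self):
        basis, cert = find_all_mcls(closed_two_cycle(), PipelineConfig(seed=0))
        assert [p.coeffs_dict for p in basis] == [{"A": 1, "B": 1}]
        assert cert.complete

    def test_triangle_gap_closed_by_extra_rounds(self):
        basis, cert = find_all_mcls(triangle_pools(), PipelineConfig(seed=3))
        assert cert.status == "saturated_bound"
        assert len(basis) == 3

    def test_mp_pruning_mode_matches_kernel_mode(self):
        model = toy_enzyme_network()
        b1, _ = find_all_mcls(model, PipelineConfig(seed=0, pruning="kernel"))
        b2, _ = find_all_mcls(model, PipelineConfig(seed=0, pruning="mp"))
        assert same_span(b1.pools, b2.pools)

    @pytest.mark.parametrize("seed", range(10))
    def test_certification_soundness_against_enumeration(self, seed):
        """Whenever the pipeline claims completeness, exhaustive enumeration
        must find no pool outside the basis span."""
        model = generate_random_network(RandomEnsembleParams(8, 10, 2, seed=seed))
        cfg = PipelineConfig(seed=seed)
        cfg.anneal.k_max = 3
        basis, cert = find_all_mcls(model, cfg)
        if not cert.complete:
            return
        bf = enumerate_mcls_bruteforce(model, k_max=3)
        span = same_span(basis.pools, bf.basis.pools)
        assert span and coverage_of(basis.pools) == coverage_of(bf.basis.pools)

    @pytest.mark.parametrize("seed", range(5))
    def test_driver_is_deterministic(self, seed):
        model = generate_random_network(RandomEnsembleParams(10, 12, 2, seed=40 + seed))
        runs = [find_all_mcls(model, PipelineConfig(seed=seed)) for _ in range(2)]
        (b1, c1), (b2, c2) = runs
        assert [p.coeffs for p in b1] == [p.coeffs for p in b2]
        assert c1.status == c2.status

    def test_medium_enrichment_never_creates_pools(self):
        """Opening an exchange can only destroy conservation laws: the
        covered set under the rich medium is contained in the closed one."""
        model, truth = plant_pools(15, 24, [{"X": 1, "Y": 1}, {"U": 1, "V": 1, "W": 2}],
                                   c=1.0, seed=5)
        closed = apply_medium(model, MediumSpec("custom", []))
        b_closed, _ = find_all_mcls(closed, PipelineConfig(seed=1))
        b_rich, _ = find_all_mcls(model, PipelineConfig(seed=1))
        assert coverage_of(b_rich.pools) <= coverage_of(b_closed.pools)
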