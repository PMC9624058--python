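"""Candidate pools, truncation selection, OCS, and crossing plans."""

import numpy as np
import pytest

from recsel.founder_genomes import generate_founders
from recsel.selection_engine import (Candidate, CandidatePool,
                                     ContributionVector, OcsInfeasibleError,
                                     OcsProblem, candidate_pool,
                                     contributions_to_crosses,
                                     ocs_contributions, random_pair_crosses,
                                     truncation_select)


def _pool(values, ids=None, births=None, policy="discrete"):
    class _Stub:
        def __init__(self, i):
            self.id = i

    ids = ids if ids is not None else list(range(len(values)))
    births = births if births is not None else [0] * len(values)
    return CandidatePool(
        candidates=[Candidate(_Stub(i), float(v), b)
                    for i, v, b in zip(ids, values, births)], policy=policy)


class TestTruncation:
    def test_selects_largest(self):
        sel = truncation_select(_pool([3, 1, 4, 1, 5]), 2)
        assert sorted(c.value for c in sel) == [4, 5]

    def test_whole_pool(self):
        assert len(truncation_select(_pool([1, 2, 3]), 3)) == 3

    def test_pool_too_small(self):
        with pytest.raises(ValueError):
            truncation_select(_pool([1, 2]), 3)

    def test_ties_broken_by_smallest_id(self):
        sel = truncation_select(_pool([2, 2, 2, 1], ids=[9, 3, 5, 1]), 2)
        assert [c.individual.id for c in sel] == [3, 5]

    def test_invariant_to_constant_shift(self):
        v = [0.3, -1.2, 2.0, 0.9, 0.1]
        a = truncation_select(_pool(v), 2)
        b = truncation_select(_pool([x + 100 for x in v]), 2)
        assert [c.individual.id for c in a] == [c.individual.id for c in b]


class TestCandidatePool:
    def test_first_cycle_policies_identical(self):
        hist = _pool([1, 2, 3], births=[1, 1, 1]).candidates
        d = candidate_pool(hist, "discrete", 1)
        o = candidate_pool(hist, "overlapping", 1)
        assert len(d) == len(o) == 3

    def test_overlapping_accumulates(self):
        hist = []
        for cyc in (1, 2, 3):
            hist.extend(_pool([1] * 100, ids=range(cyc * 100, cyc * 100 + 100),
                              births=[cyc] * 100).candidates)
        assert len(candidate_pool(hist, "overlapping", 3)) == 300
        assert len(candidate_pool(hist, "discrete", 3)) == 100

    def test_frozen_criterion_values(self):
        hist = _pool([1.25, 2.5], births=[1, 1]).candidates
        v0 = hist[0].value
        for cyc in (2, 3):
            hist.extend(_pool([9], ids=[50 + cyc], births=[cyc]).candidates)
            pool = candidate_pool(hist, "overlapping", cyc)
            assert pool.candidates[0].value == v0

    def test_missing_current_cycle(self):
        hist = _pool([1, 2], births=[1, 1]).candidates
        with pytest.raises(ValueError):
            candidate_pool(hist, "discrete", 2)


def _grid_eval(g, K, theta, grids):
    """Best objective over an explicit list of per-coordinate grids."""
    mesh = np.stack(np.meshgrid(*grids[:3], indexing="ij"), axis=-1)
    C = mesh.reshape(-1, 3)
    last = 1.0 - C.sum(axis=1)
    ok = (last >= -1e-12) & np.all(C >= -1e-12, axis=1)
    C = np.column_stack([C[ok], np.clip(last[ok], 0.0, None)])
    feas = np.einsum("ij,jk,ik->i", C, K, C) <= theta + 1e-12
    if not feas.any():
        return -np.inf, None
    vals = C[feas] @ g
    i = int(vals.argmax())
    return float(vals[i]), C[feas][i]


def _grid_optimum(g, K, theta, step=0.01, refine=0.0005):
    """Brute-force oracle: exhaustive simplex grid search with one local
    refinement pass around the coarse argmax (4 candidates)."""
    assert len(g) == 4
    coarse = [np.arange(0.0, 1.0 + step / 2, step)] * 3
    best, c = _grid_eval(g, K, theta, coarse)
    if c is None:
        return best
    local = [np.clip(np.arange(ci - 2 * step, ci + 2 * step + refine / 2,
                               refine), 0.0, 1.0) for ci in c[:3]]
    best2, _ = _grid_eval(g, K, theta, local)
    return max(best, best2)


class TestOcs:
    def test_slack_constraint_picks_best(self):
        problem = OcsProblem(gebv=np.array([1.0, 3.0]),
                             kinship=0.5 * np.eye(2), min_Ne=1.0,
                             current_mean_kinship=0.25)
        c = ocs_contributions(problem).contributions
        assert c[1] > 0.99

    def test_equal_merit_symmetric_solution(self):
        # equal GEBVs, unrelated non-inbred candidates, binding constraint:
        # minimum-coancestry symmetry gives equal contributions.
        K = 0.5 * np.eye(4)
        problem = OcsProblem(gebv=np.ones(4), kinship=K, min_Ne=100.0,
                             current_mean_kinship=0.13)
        c = ocs_contributions(problem).contributions
        assert np.allclose(c, 0.25, atol=1e-4)
        assert _grid_optimum(np.ones(4), K, problem.theta) == pytest.approx(
            1.0)

    def test_matches_grid_oracle(self):
        rng = np.random.default_rng(7)
        for trial in range(3):
            n = 4
            g = rng.normal(size=n)
            A = rng.normal(size=(n, n)) * 0.1
            K = A @ A.T + 0.5 * np.eye(n)
            kbar = float(K.mean())
            problem = OcsProblem(gebv=g, kinship=K, min_Ne=20.0,
                                 current_mean_kinship=kbar)
            c = ocs_contributions(problem).contributions
            obj = c @ g
            grid = _grid_optimum(g, K, problem.theta)
            assert obj >= grid - 1e-3  # solver is never beaten by the grid
            assert abs(obj - grid) < 1e-3
            assert c @ K @ c <= problem.theta + 1e-7

    def test_objective_bounded_by_truncation_optimum(self):
        rng = np.random.default_rng(1)
        g = rng.normal(size=6)
        K = 0.5 * np.eye(6)
        problem = OcsProblem(gebv=g, kinship=K, min_Ne=10.0,
                             current_mean_kinship=float(K.mean()))
        c = ocs_contributions(problem).contributions
        assert c @ g <= g.max() + 1e-9

    def test_monotone_in_theta(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            n = 5
            g = rng.normal(size=n)
            A = rng.normal(size=(n, n)) * 0.2
            K = A @ A.T + 0.5 * np.eye(n)
            objs = []
            for ne in (200.0, 20.0, 2.0):  # decreasing Ne = looser theta
                problem = OcsProblem(gebv=g, kinship=K, min_Ne=ne,
                                     current_mean_kinship=float(K.mean()))
                objs.append(ocs_contributions(problem).contributions @ g)
            assert objs[0] <= objs[1] + 1e-6 <= objs[2] + 2e-6

    def test_infeasible_raises_with_diagnostics(self):
        # everyone fully related: mean kinship 1 regardless of c, but the
        # scheduled bound asks for less.
        K = np.ones((3, 3))
        problem = OcsProblem(gebv=np.arange(3.0), kinship=K, min_Ne=50.0,
                             current_mean_kinship=0.2)
        with pytest.raises(OcsInfeasibleError) as err:
            ocs_contributions(problem)
        assert err.value.min_achievable == pytest.approx(1.0, abs=1e-6)
        assert err.value.theta < 1.0

    def test_problem_validation(self):
        with pytest.raises(ValueError):
            OcsProblem(gebv=np.array([1.0]), kinship=np.eye(1), min_Ne=10,
                       current_mean_kinship=0.0)


class TestCrossingPlans:
    def test_equal_contributions_use_both(self, rng):
        cv = ContributionVector(np.array([0.5, 0.5]))
        plan = contributions_to_crosses(cv, 200, 1, rng)
        for x in plan:
            assert {x.mother_idx, x.father_idx} == {0, 1}

    def test_single_parent_rejected(self, rng):
        cv = ContributionVector(np.array([1.0, 0.0, 0.0]))
        with pytest.raises(ValueError, match="selfing"):
            contributions_to_crosses(cv, 10, 1, rng)

    def test_usage_matches_enumerated_expectation(self, rng):
        c = np.array([0.7, 0.2, 0.1])
        # exact per-cross usage probability under distinct-pair sampling
        expect = np.array([
            c[i] + sum(c[j] * c[i] / (1 - c[j]) for j in range(3) if j != i)
            for i in range(3)])
        n = 10_000
        plan = contributions_to_crosses(ContributionVector(c), n, 1, rng)
        usage = np.zeros(3)
        for x in plan:
            usage[x.mother_idx] += 1
            usage[x.father_idx] += 1
        freq = usage / n
        se = np.sqrt(expect * (1 - expect) / n) + np.sqrt(expect / n)
        assert np.all(np.abs(freq - expect) < 4 * se)

    def test_random_pairs_distinct(self, rng):
        plan = random_pair_crosses(5, 100, 2, rng)
        assert all(x.mother_idx != x.father_idx for x in plan)
        assert all(x.n_progeny == 2 for x in plan)
        with pytest.raises(ValueError):
            random_pair_crosses(1, 5, 1, rng)

    def test_contribution_vector_validation(self):
        with pytest.raises(ValueError):
            ContributionVector(np.array([0.5, 0.2]))  # does not sum to 1
        with pytest.raises(ValueError):
            ContributionVector(np.array([1.2, -0.2]))


class TestKinshipIntegration:
    def test_ocs_on_real_ibd_kinship(self, small_spec):
        from recsel.founder_genomes import kinship_matrix, make_cross

        pop = generate_founders(small_spec, 8, seed=5)
        rng = np.random.default_rng(3)
        inds = list(pop.individuals)
        # add two full-sib families to create kinship structure
        for k in range(2):
            inds.extend(make_cross(inds[k], inds[k + 2], 3, 1, rng,
                                   small_spec, first_id=100 + 10 * k))
        K = kinship_matrix(inds)
        g = np.random.default_rng(0).normal(size=len(inds))
        problem = OcsProblem(gebv=g, kinship=K, min_Ne=45.0,
                             current_mean_kinship=float(K.mean()))
        c = ocs_contributions(problem).contributions
        assert c @ K @ c <= problem.theta + 1e-7
        assert abs(c.sum() - 1.0) < 1e-8
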