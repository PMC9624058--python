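"""Candidate pools, truncation selection, optimum contribution selection
(OCS), and conversion of contributions into a crossing plan.

The pool policy is the study's central contrast: under *discrete*
generations only the current cycle's cohort is eligible; under
*overlapping* generations every cohort ever evaluated remains eligible.
Phenotype criterion values are frozen at the original evaluation, while
GEBVs are refreshed from the current marker model each cycle.

OCS maximizes mean parental merit c'g over contribution vectors c on the
simplex, subject to a bound on next-generation mean kinship
c'Kc <= theta, theta = kbar + (1 - kbar) * dF with dF = 1/(2 Ne). The
convex program is solved with SLSQP plus a feasibility pre-check and a
minimum-coancestry tie-break pass.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .founder_genomes import Individual

CONTRIBUTION_TOL = 1e-6  # contributions below this count as unused parents


@dataclass
class Candidate:
    individual: Individual
    value: float
    birth_cycle: int
    provenance: str = "phenotype"  # phenotype | tbv | gebv


@dataclass
class CandidatePool:
    candidates: list[Candidate]
    policy: str  # discrete | overlapping

    def __post_init__(self) -> None:
        if self.policy not in ("discrete", "overlapping"):
            raise ValueError(f"unknown policy: {self.policy!r}")

    def __len__(self) -> int:
        return len(self.candidates)

    @property
    def values(self) -> np.ndarray:
        return np.array([c.value for c in self.candidates])

    @property
    def individuals(self) -> list[Individual]:
        return [c.individual for c in self.candidates]


def candidate_pool(history: list[Candidate], policy: str,
                   current_cycle: int) -> CandidatePool:
    """Assemble the eligible candidates under a generation policy."""
    if not any(c.birth_cycle == current_cycle for c in history):
        raise ValueError("history does not contain the current cycle")
    if policy == "discrete":
        kept = [c for c in history if c.birth_cycle == current_cycle]
    else:
        kept = list(history)
    return CandidatePool(candidates=kept, policy=policy)


def truncation_select(pool: CandidatePool, n: int) -> list[Candidate]:
    """The n candidates with the largest criterion values.

    Ties are broken by smallest individual id (stable and documented).
    """
    if len(pool) < n:
        raise ValueError(f"pool of {len(pool)} smaller than n={n}")
    ranked = sorted(pool.candidates, key=lambda c: (-c.value, c.individual.id))
    return ranked[:n]


class OcsInfeasibleError(RuntimeError):
    """The kinship constraint cannot be met by any contribution vector.

    Carries the minimum achievable mean kinship; in long-running programs
    with tight effective-population-size floors this is the expected
    failure mode once coancestry accumulates.
    """

    def __init__(self, min_achievable: float, theta: float):
        super().__init__(
            f"OCS infeasible: min achievable c'Kc={min_achievable:.6f} "
            f"> bound theta={theta:.6f}")
        self.min_achievable = min_achievable
        self.theta = theta


@dataclass
class OcsProblem:
    gebv: np.ndarray
    kinship: np.ndarray
    min_Ne: float
    current_mean_kinship: float

    def __post_init__(self) -> None:
        self.kinship = 0.5 * (self.kinship + self.kinship.T)
        if self.gebv.shape[0] != self.kinship.shape[0]:
            raise ValueError("merit vector and kinship matrix sizes differ")
        if self.gebv.shape[0] < 2:
            raise ValueError("OCS needs at least 2 candidates")

    @property
    def delta_F(self) -> float:
        return 1.0 / (2.0 * self.min_Ne)

    @property
    def theta(self) -> float:
        """Bound on next-generation mean kinship at inbreeding rate dF."""
        k = self.current_mean_kinship
        return k + (1.0 - k) * self.delta_F


@dataclass
class ContributionVector:
    contributions: np.ndarray

    def __post_init__(self) -> None:
        c = self.contributions
        if np.any(c < -1e-9) or abs(c.sum() - 1.0) > 1e-6:
            raise ValueError("contributions must be a point on the simplex")
        self.contributions = np.clip(c, 0.0, None)
        self.contributions /= self.contributions.sum()

    @property
    def support(self) -> np.ndarray:
        return np.flatnonzero(self.contributions > CONTRIBUTION_TOL)


def _simplex_constraints(n: int):
    return [{"type": "eq", "fun": lambda c: c.sum() - 1.0,
             "jac": lambda c: np.ones(n)}]


def _min_kinship_point(K: np.ndarray) -> tuple[np.ndarray, float]:
    n = K.shape[0]
    res = minimize(
        lambda c: c @ K @ c, np.full(n, 1.0 / n), jac=lambda c: 2.0 * K @ c,
        bounds=[(0.0, 1.0)] * n, constraints=_simplex_constraints(n),
        method="SLSQP", options={"maxiter": 500, "ftol": 1e-12})
    c = np.clip(res.x, 0.0, None)
    c /= c.sum()
    return c, float(c @ K @ c)


def ocs_contributions(problem: OcsProblem) -> ContributionVector:
    """Solve the OCS convex program.

    maximize c'g  s.t.  c'Kc <= theta, c >= 0, sum(c) = 1.
    Among solutions within 1e-8 of the optimum, the minimum-c'Kc one is
    returned (deterministic tie-break for degenerate merit ties).
    """
    g, K, theta = problem.gebv, problem.kinship, problem.theta
    n = g.shape[0]
    c_min, k_min = _min_kinship_point(K)
    if k_min > theta + 1e-9:
        raise OcsInfeasibleError(k_min, theta)

    cons = _simplex_constraints(n) + [
        {"type": "ineq", "fun": lambda c: theta - c @ K @ c,
         "jac": lambda c: -2.0 * K @ c}]
    # Two deterministic starts: the min-kinship point and a blend toward the
    # best candidate; keep the better optimum.
    best = None
    e_top = np.zeros(n)
    e_top[int(np.lexsort((np.arange(n), -g))[0])] = 1.0
    for x0 in (c_min, 0.5 * c_min + 0.5 * e_top, np.full(n, 1.0 / n)):
        res = minimize(
            lambda c: -(c @ g), x0, jac=lambda c: -g,
            bounds=[(0.0, 1.0)] * n, constraints=cons, method="SLSQP",
            options={"maxiter": 500, "ftol": 1e-12})
        c = np.clip(res.x, 0.0, None)
        s = c.sum()
        if s <= 0:
            continue
        c /= s
        if c @ K @ c > theta + 1e-7:
            continue
        if best is None or c @ g > best @ g:
            best = c
    if best is None:  # constraint active everywhere: fall back to feasible point
        best = c_min
    obj = float(best @ g)

    # Tie-break: minimize coancestry among near-optimal solutions.
    cons2 = _simplex_constraints(n) + [
        {"type": "ineq", "fun": lambda c: c @ g - (obj - 1e-8),
         "jac": lambda c: g},
        {"type": "ineq", "fun": lambda c: theta - c @ K @ c,
         "jac": lambda c: -2.0 * K @ c}]
    res2 = minimize(
        lambda c: c @ K @ c, best, jac=lambda c: 2.0 * K @ c,
        bounds=[(0.0, 1.0)] * n, constraints=cons2, method="SLSQP",
        options={"maxiter": 500, "ftol": 1e-12})
    if res2.success:
        c2 = np.clip(res2.x, 0.0, None)
        c2 /= c2.sum()
        if c2 @ g >= obj - 1e-7 and c2 @ K @ c2 <= theta + 1e-7:
            best = c2
    return ContributionVector(contributions=best)


@dataclass
class Cross:
    mother_idx: int
    father_idx: int
    n_progeny: int


def contributions_to_crosses(contribs: ContributionVector, n_crosses: int,
                             n_progeny_per_cross: int,
                             rng: np.random.Generator) -> list[Cross]:
    """Sample a crossing plan proportional to contributions.

    Each cross draws two distinct parents with probability proportional to
    their contributions (the second parent from the renormalized remainder),
    so expected parental usage tracks c. Selfing is disabled: a plan with a
    single positive contribution is rejected.
    """
    c = contribs.contributions
    support = contribs.support
    if support.size < 2:
        raise ValueError("need >= 2 parents with positive contribution "
                         "(selfing is disabled)")
    plan = []
    for _ in range(n_crosses):
        mother = rng.choice(len(c), p=c)
        rest = c.copy()
        rest[mother] = 0.0
        rest /= rest.sum()
        father = rng.choice(len(c), p=rest)
        plan.append(Cross(int(mother), int(father), n_progeny_per_cross))
    return plan


def random_pair_crosses(n_parents: int, n_crosses: int, n_progeny_per_cross: int,
                        rng: np.random.Generator) -> list[Cross]:
    """Random biparental crosses among selected parents (no selfing)."""
    if n_parents < 2:
        raise ValueError("need >= 2 parents to cross")
    plan = []
    for _ in range(n_crosses):
        i, j = rng.choice(n_parents, size=2, replace=False)
        plan.append(Cross(int(i), int(j), n_progeny_per_cross))
    return plan


def crossing_plan_frame(plan: list[Cross], parents: list[Individual]):
    """Serialize a crossing plan to a DataFrame (cross_id, parent ids)."""
    import pandas as pd

    return pd.DataFrame(
        [{"cross_id": k, "mother_id": parents[x.mother_idx].id,
          "father_id": parents[x.father_idx].id, "n_progeny": x.n_progeny}
         for k, x in enumerate(plan)])
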