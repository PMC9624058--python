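"""The two breeding-program architectures.

RS-A: recurrent mass selection on a purely additive trait, one cohort per
cycle. Each cycle 100 random biparental crosses of the selected parents
produce 100 progeny (one per cross); candidates are evaluated on phenotype,
true breeding value, or GEBV; 20 parents are chosen by truncation, or
parental contributions by optimum contribution selection under a
minimum-Ne kinship bound. Under the discrete policy only the current
cohort is eligible; under the overlapping policy all past cohorts remain
candidates, with phenotypes frozen at first evaluation but GEBVs refreshed
from the current marker model.

RS-AY: a multi-stage doubled-haploid pipeline on a trait with additive,
year, and additive-by-year effects (compound symmetry). 30 parents are
crossed into biparental families, progeny are converted to doubled
haploids, and cohorts move through headrows, a preliminary yield trial
(PYT), an advanced yield trial (AYT) and two elite yield trial years (EYT),
with stage heritabilities 0.1 / 0.2 / 0.5 / 0.8 and truncation advancement.
Parents are the top-ranked PYT entries plus the individuals advanced out of
the AYT (the current first-year EYT cohort), evaluated on their
current-year records, which is why the year component of selection error
bias is exactly 1 under discrete generations: every candidate shares the
same year effect.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .founder_genomes import (GenomeSpec, Individual, generate_founders,
                              ibd_inbreeding, kinship_matrix, make_cross,
                              make_dh)
from .genomic_prediction import (MarkerModel, PhenotypeArchive,
                                 build_training_set, fit_rrblup, predict_gebv)
from .metrics import (ErrorDecomposition, decompose_error_bias, genetic_stats,
                      mean_parental_age, selection_accuracy,
                      selection_error_bias)
from .selection_engine import (Candidate, CandidatePool, OcsInfeasibleError,
                               OcsProblem, candidate_pool,
                               contributions_to_crosses, ocs_contributions,
                               random_pair_crosses, truncation_select)
from .trait_architecture import (EnvironmentModel, HeritabilitySpec,
                                 PhenotypeRecord, TraitModel,
                                 assign_qtl_effects, make_phenotypes,
                                 sample_site_roles, true_breeding_values)

logger = logging.getLogger(__name__)

METRIC_COLUMNS = [
    "cycle", "mean_genetic_value", "genetic_variance", "selection_error_bias",
    "bias_year", "bias_gxy", "bias_plot", "inbreeding", "accuracy",
    "mean_parental_age", "n_candidates", "n_selected", "steady_state",
]


@dataclass
class RsaConfig:
    """One RS-A scenario (a cell of the factor grid)."""

    h2: float = 0.1
    policy: str = "discrete"  # discrete | overlapping
    criterion: str = "phenotype"  # phenotype | tbv | gebv
    n_reps_phenotype: int = 1  # 1 or 3; only meaningful for phenotype
    gs_mode: str = "truncation"  # truncation | ocs; only for gebv
    training_window: str = "allGen"  # allGen | fiveGen; only for gebv
    min_Ne: float = 45.0  # only for ocs
    # "measured": the kinship bound is rebuilt each cycle from the current
    # candidate pool's mean kinship (always feasible). "scheduled": the
    # bound follows the recursion theta_t = theta_{t-1} + (1-theta_{t-1})dF
    # from the base population, which can become infeasible once realized
    # coancestry outruns the scheduled inbreeding path.
    ocs_theta_mode: str = "measured"
    n_founders: int = 100
    n_parents: int = 20
    n_crosses: int = 100
    progeny_per_cross: int = 1
    n_cycles: int = 50
    genome: GenomeSpec = field(default_factory=GenomeSpec)

    def __post_init__(self) -> None:
        if self.policy not in ("discrete", "overlapping"):
            raise ValueError(f"unknown policy {self.policy!r}")
        if self.criterion not in ("phenotype", "tbv", "gebv"):
            raise ValueError(f"unknown criterion {self.criterion!r}")
        if self.gs_mode not in ("truncation", "ocs"):
            raise ValueError(f"unknown gs_mode {self.gs_mode!r}")
        if self.criterion != "phenotype" and self.n_reps_phenotype != 1:
            raise ValueError("replication applies to phenotypic selection only")
        if self.ocs_theta_mode not in ("measured", "scheduled"):
            raise ValueError(f"unknown ocs_theta_mode {self.ocs_theta_mode!r}")


@dataclass
class ProgramState:
    """Mutable state threaded through breeding cycles."""

    spec: GenomeSpec
    trait: TraitModel
    archive: PhenotypeArchive
    rng: np.random.Generator
    history: list[Candidate] = field(default_factory=list)
    parents: list[Individual] = field(default_factory=list)
    contributions: np.ndarray | None = None
    pool_individuals: list[Individual] | None = None
    marker_model: MarkerModel | None = None
    env: EnvironmentModel | None = None
    ocs_theta: float | None = None  # scheduled-mode kinship bound
    next_id: int = 0
    cycle: int = 0
    rows: list[dict] = field(default_factory=list)
    truncated_at: int | None = None


def _phenotype_cohort(state: ProgramState, cohort: list[Individual],
                      herit: HeritabilitySpec, cycle: int,
                      stage: str = "") -> list[PhenotypeRecord]:
    records = make_phenotypes(cohort, state.trait, herit, state.rng,
                              env=state.env, year=cycle, stage=stage)
    state.archive.add(cohort, np.array([r.phenotype for r in records]),
                      cycle, stage=stage)
    return records


def init_rsa(cfg: RsaConfig, seed: int) -> ProgramState:
    """Cycle 0: founders are phenotyped and 20 parents selected on phenotype."""
    ss = np.random.SeedSequence([int(seed), 1])
    s_founder, s_trait, s_run = ss.spawn(3)
    founders = generate_founders(cfg.genome, cfg.n_founders, s_founder)
    rng = np.random.default_rng(s_run)
    qtl_sites, chip_sites = sample_site_roles(cfg.genome, rng)
    trait = assign_qtl_effects(founders, qtl_sites, 1.0,
                               s_trait.generate_state(1)[0] % (2 ** 31))
    state = ProgramState(spec=cfg.genome, trait=trait,
                         archive=PhenotypeArchive(chip_sites=chip_sites),
                         rng=rng, next_id=cfg.n_founders)
    n_reps = cfg.n_reps_phenotype if cfg.criterion == "phenotype" else 1
    herit = HeritabilitySpec(value=cfg.h2, kind="narrow", n_reps=n_reps)
    records = _phenotype_cohort(state, founders.individuals, herit, cycle=0)
    # First-year parent selection is phenotypic in every scenario, but the
    # founders enter later candidate pools carrying the scenario's own
    # criterion (their TBV under TBV selection; GEBVs are refreshed anyway).
    if cfg.criterion == "tbv":
        tbvs = true_breeding_values(founders.individuals, trait)
        values = [float(t) for t in tbvs]
    else:
        values = [r.phenotype for r in records]
    state.history = [
        Candidate(individual=ind, value=v, birth_cycle=0,
                  provenance=cfg.criterion)
        for ind, v in zip(founders.individuals, values)]
    initial = CandidatePool(
        candidates=[Candidate(ind, r.phenotype, 0, "phenotype")
                    for ind, r in zip(founders.individuals, records)],
        policy="discrete")
    state.parents = [c.individual
                     for c in truncation_select(initial, cfg.n_parents)]
    return state


def _rsa_crossing_plan(state: ProgramState, cfg: RsaConfig):
    if state.contributions is not None:
        plan = contributions_to_crosses(
            state.contributions, cfg.n_crosses, cfg.progeny_per_cross,
            state.rng)
        pool = state.pool_individuals
        return [(pool[x.mother_idx], pool[x.father_idx], x.n_progeny)
                for x in plan]
    plan = random_pair_crosses(len(state.parents), cfg.n_crosses,
                               cfg.progeny_per_cross, state.rng)
    return [(state.parents[x.mother_idx], state.parents[x.father_idx],
             x.n_progeny) for x in plan]


def run_rsa_cycle(state: ProgramState, cfg: RsaConfig) -> ProgramState:
    """Advance one RS-A breeding cycle: cross, evaluate, select, record."""
    cycle = state.cycle + 1
    state.cycle = cycle

    # Parental age is the generation interval: offspring birth cycle minus
    # the parent's own birth cycle, recorded at crossing time.
    plan = _rsa_crossing_plan(state, cfg)
    used = []
    progeny: list[Individual] = []
    for mother, father, k in plan:
        used.extend([mother, father])
        progeny.extend(make_cross(mother, father, k, cycle, state.rng,
                                  cfg.genome, first_id=state.next_id))
        state.next_id += k
    parental_age = mean_parental_age(used, cycle)

    n_reps = cfg.n_reps_phenotype if cfg.criterion == "phenotype" else 1
    herit = HeritabilitySpec(value=cfg.h2, kind="narrow", n_reps=n_reps)
    records = _phenotype_cohort(state, progeny, herit, cycle)

    if cfg.criterion == "phenotype":
        new = [Candidate(ind, r.phenotype, cycle, "phenotype")
               for ind, r in zip(progeny, records)]
        state.history.extend(new)
    elif cfg.criterion == "tbv":
        tbvs = true_breeding_values(progeny, state.trait)
        new = [Candidate(ind, float(t), cycle, "tbv")
               for ind, t in zip(progeny, tbvs)]
        state.history.extend(new)
    else:  # gebv: refit and re-score the whole pool with the current model
        training = build_training_set(state.archive, cfg.training_window,
                                      cycle)
        state.marker_model = fit_rrblup(training)
        new = [Candidate(ind, 0.0, cycle, "gebv") for ind in progeny]
        state.history.extend(new)
        gebvs = predict_gebv(state.marker_model,
                             [c.individual for c in state.history])
        for cand, v in zip(state.history, gebvs):
            cand.value = float(v)

    pool = candidate_pool(state.history, cfg.policy, cycle)
    mean_tbv, var_tbv = genetic_stats(progeny, state.trait)

    row = {"cycle": cycle, "mean_genetic_value": mean_tbv,
           "genetic_variance": var_tbv, "n_candidates": len(pool),
           "steady_state": True}
    try:
        if cfg.criterion == "gebv" and cfg.gs_mode == "ocs":
            K = kinship_matrix(pool.individuals)
            if cfg.ocs_theta_mode == "measured":
                kbar = float(K.mean())
            else:  # scheduled: advance theta along the target dF path
                kbar = (state.ocs_theta if state.ocs_theta is not None
                        else float(K.mean()))
            problem = OcsProblem(gebv=pool.values, kinship=K,
                                 min_Ne=cfg.min_Ne,
                                 current_mean_kinship=kbar)
            state.ocs_theta = problem.theta
            contribs = ocs_contributions(problem)
            if contribs.support.size < 2:
                # Slack constraint puts all mass on one candidate; selfing
                # is disabled, so fall back to truncation for this cycle.
                logger.info("cycle %d: OCS degenerate to one parent; "
                            "using truncation", cycle)
                selected = truncation_select(pool, cfg.n_parents)
                state.parents = [c.individual for c in selected]
                state.contributions = None
                state.pool_individuals = None
            else:
                state.contributions = contribs
                state.pool_individuals = pool.individuals
                selected = [pool.candidates[i] for i in contribs.support]
                state.parents = [c.individual for c in selected]
        else:
            selected = truncation_select(pool, cfg.n_parents)
            state.parents = [c.individual for c in selected]
            state.contributions = None
            state.pool_individuals = None
    except OcsInfeasibleError as err:
        logger.warning("cycle %d: %s", cycle, err)
        state.truncated_at = cycle
        row.update({"selection_error_bias": np.nan, "bias_year": np.nan,
                    "bias_gxy": np.nan, "bias_plot": np.nan,
                    "inbreeding": np.nan, "accuracy": np.nan,
                    "mean_parental_age": parental_age,
                    "n_selected": 0})
        state.rows.append(row)
        return state

    sel_values = np.array([c.value for c in selected])
    sel_tbvs = true_breeding_values([c.individual for c in selected],
                                    state.trait)
    all_tbvs = true_breeding_values(pool.individuals, state.trait)
    bias = selection_error_bias(sel_values - sel_tbvs, pool.values - all_tbvs)
    row.update({
        "selection_error_bias": bias,
        "bias_year": np.nan, "bias_gxy": np.nan,
        "bias_plot": bias if cfg.criterion == "phenotype" else np.nan,
        "inbreeding": ibd_inbreeding(state.parents),
        # selection on TBV itself is exact by definition
        "accuracy": (1.0 if cfg.criterion == "tbv"
                     else selection_accuracy(sel_values, sel_tbvs)),
        "mean_parental_age": parental_age,
        "n_selected": len(selected)})
    state.rows.append(row)
    return state


def run_rsa_scenario(cfg: RsaConfig, seed: int) -> pd.DataFrame:
    """Run one RS-A scenario; one metrics row per completed cycle.

    On OCS infeasibility the scenario is truncated (logged; remaining
    cycles absent and ``attrs['truncated_at']`` set).
    """
    state = init_rsa(cfg, seed)
    for _ in range(cfg.n_cycles):
        run_rsa_cycle(state, cfg)
        if state.truncated_at is not None:
            break
    frame = pd.DataFrame(state.rows, columns=METRIC_COLUMNS)
    frame.attrs["truncated_at"] = state.truncated_at
    return frame


# ---------------------------------------------------------------------------
# RS-AY: multi-stage doubled-haploid pipeline
# ---------------------------------------------------------------------------

TRAINING_STAGES = {"pyt", "ayt", "eyt1", "eyt2"}


@dataclass
class RsayConfig:
    """One RS-AY scenario.

    Defaults are the full-scale program: 100 crosses x 97 progeny, headrow
    -> 500 -> 50 -> 10 advancement, 20 + 10 parents, 40 years. The
    ``reduced()`` preset shrinks cohort sizes (keeping the 2:1 parent-source
    ratio, which preserves the structural parental-age constant) for
    desk-scale runs.
    """

    policy: str = "discrete"
    criterion: str = "phenotype"  # phenotype | gebv
    n_parents_stage4: int = 20
    n_parents_stage5: int = 10
    n_crosses: int = 100
    progeny_per_cross: int = 97
    advance_headrow: int = 500
    advance_pyt: int = 50
    advance_ayt: int = 10
    h2_headrow: float = 0.1
    h2_pyt: float = 0.2
    h2_ayt: float = 0.5
    h2_eyt: float = 0.8
    year_effect_variance: float = 0.2
    gxy_variance: float = 0.2
    n_founders: int = 100
    founder_h2: float = 0.2
    n_years: int = 40
    genome: GenomeSpec = field(default_factory=GenomeSpec)

    def __post_init__(self) -> None:
        if self.policy not in ("discrete", "overlapping"):
            raise ValueError(f"unknown policy {self.policy!r}")
        if self.criterion not in ("phenotype", "gebv"):
            raise ValueError(f"unknown criterion {self.criterion!r}")
        sizes = (self.n_crosses * self.progeny_per_cross, self.advance_headrow,
                 self.advance_pyt, self.advance_ayt)
        if any(a <= b for a, b in zip(sizes, sizes[1:])):
            raise ValueError("stage sizes must strictly decrease")
        if self.n_parents_stage4 > self.advance_headrow:
            raise ValueError("stage-4 parent count exceeds PYT cohort size")
        if self.n_parents_stage5 > self.advance_ayt:
            raise ValueError("stage-5 parent count exceeds EYT cohort size")

    @property
    def n_parents(self) -> int:
        return self.n_parents_stage4 + self.n_parents_stage5

    @classmethod
    def reduced(cls, **overrides) -> "RsayConfig":
        base = dict(n_crosses=15, progeny_per_cross=8, advance_headrow=60,
                    advance_pyt=20, advance_ayt=5, n_parents_stage4=10,
                    n_parents_stage5=5, n_years=15)
        base.update(overrides)
        return cls(**base)


@dataclass
class _RsayCandidate:
    individual: Individual
    value: float
    record: PhenotypeRecord | None  # None for GEBV criterion


@dataclass
class RsayState:
    spec: GenomeSpec
    trait: TraitModel
    env: EnvironmentModel
    archive: PhenotypeArchive
    rng: np.random.Generator
    founder_ranked: list[Individual]  # founders ranked by initial phenotype
    stages: dict = field(default_factory=dict)  # cohort entering each stage
    pyt_history: list = field(default_factory=list)  # _RsayCandidate, frozen
    eyt1_history: list = field(default_factory=list)
    pyt_inds: list = field(default_factory=list)  # individuals ever in PYT
    eyt1_inds: list = field(default_factory=list)
    eyt1_pheno: dict = field(default_factory=dict)  # id -> EYT1 phenotype
    marker_model: MarkerModel | None = None
    parents: list[Individual] = field(default_factory=list)
    next_id: int = 0
    year: int = 0
    rows: list[dict] = field(default_factory=list)


def init_rsay(cfg: RsayConfig, seed: int) -> RsayState:
    """Found the program: founders phenotyped once, top 30 become parents."""
    ss = np.random.SeedSequence([int(seed), 2])
    s_founder, s_trait, s_env, s_run = ss.spawn(4)
    founders = generate_founders(cfg.genome, cfg.n_founders, s_founder)
    rng = np.random.default_rng(s_run)
    qtl_sites, chip_sites = sample_site_roles(cfg.genome, rng)
    trait = assign_qtl_effects(founders, qtl_sites, 1.0,
                               s_trait.generate_state(1)[0] % (2 ** 31))
    env = EnvironmentModel(
        year_effect_variance=cfg.year_effect_variance,
        gxy_target_variance=cfg.gxy_variance,
        base_seed=int(s_env.generate_state(1)[0] % (2 ** 31)))
    state = RsayState(spec=cfg.genome, trait=trait, env=env,
                      archive=PhenotypeArchive(chip_sites=chip_sites),
                      rng=rng, founder_ranked=[], next_id=cfg.n_founders)
    herit = HeritabilitySpec(value=cfg.founder_h2, kind="broad")
    records = make_phenotypes(founders.individuals, trait, herit, rng,
                              env=env, year=0, stage="founder")
    order = sorted(range(len(records)),
                   key=lambda i: (-records[i].phenotype, founders.individuals[i].id))
    state.founder_ranked = [founders.individuals[i] for i in order]
    state.parents = state.founder_ranked[:cfg.n_parents]
    return state


def _advance(records: list[PhenotypeRecord], cohort: list[Individual],
             n: int) -> list[Individual]:
    """Truncation advancement on the stage phenotype (ties by id)."""
    order = sorted(range(len(cohort)),
                   key=lambda i: (-records[i].phenotype, cohort[i].id))
    return [cohort[i] for i in order[:n]]


def run_rsay_year(state: RsayState, cfg: RsayConfig) -> RsayState:
    """Advance the whole pipeline by one year and select 30 parents."""
    year = state.year + 1
    state.year = year
    rng = state.rng
    herit = lambda h: HeritabilitySpec(value=h, kind="broad")  # noqa: E731
    next_stages: dict = {}

    # Stage 2: doubled haploids from last year's cross progeny. The DH
    # keeps its source's birth year (the cross year) for age accounting.
    f1 = state.stages.get("f1")
    if f1:
        dhs = []
        for p in f1:
            dhs.append(make_dh(p, p.birth_cycle, rng, cfg.genome,
                               state.next_id))
            state.next_id += 1
        next_stages["headrow"] = dhs

    # Stages 3-7: phenotype each occupied trial stage with this year's
    # shared year effect, then advance by truncation on the stage phenotype.
    pyt_cohort = state.stages.get("pyt") or []
    pyt_records: list[PhenotypeRecord] = []
    eyt1_cohort = state.stages.get("eyt1") or []
    eyt1_records: list[PhenotypeRecord] = []

    cohort = state.stages.get("headrow")
    if cohort:
        records = make_phenotypes(cohort, state.trait, herit(cfg.h2_headrow),
                                  rng, env=state.env, year=year,
                                  stage="headrow")
        next_stages["pyt"] = _advance(records, cohort, cfg.advance_headrow)

    if pyt_cohort:
        pyt_records = make_phenotypes(pyt_cohort, state.trait,
                                      herit(cfg.h2_pyt), rng, env=state.env,
                                      year=year, stage="pyt")
        state.archive.add(pyt_cohort,
                          np.array([r.phenotype for r in pyt_records]),
                          year, stage="pyt")
        state.pyt_history.extend(
            _RsayCandidate(ind, r.phenotype, r)
            for ind, r in zip(pyt_cohort, pyt_records))
        state.pyt_inds.extend(pyt_cohort)
        next_stages["ayt"] = _advance(pyt_records, pyt_cohort, cfg.advance_pyt)

    cohort = state.stages.get("ayt")
    if cohort:
        records = make_phenotypes(cohort, state.trait, herit(cfg.h2_ayt), rng,
                                  env=state.env, year=year, stage="ayt")
        state.archive.add(cohort, np.array([r.phenotype for r in records]),
                          year, stage="ayt")
        next_stages["eyt1"] = _advance(records, cohort, cfg.advance_ayt)

    if eyt1_cohort:
        eyt1_records = make_phenotypes(eyt1_cohort, state.trait,
                                       herit(cfg.h2_eyt), rng, env=state.env,
                                       year=year, stage="eyt1")
        state.archive.add(eyt1_cohort,
                          np.array([r.phenotype for r in eyt1_records]),
                          year, stage="eyt1")
        state.eyt1_history.extend(
            _RsayCandidate(ind, r.phenotype, r)
            for ind, r in zip(eyt1_cohort, eyt1_records))
        state.eyt1_inds.extend(eyt1_cohort)
        for ind, r in zip(eyt1_cohort, eyt1_records):
            state.eyt1_pheno[ind.id] = r.phenotype
        next_stages["eyt2"] = list(eyt1_cohort)

    variety_tbv = np.nan
    cohort = state.stages.get("eyt2")
    if cohort:
        records = make_phenotypes(cohort, state.trait, herit(cfg.h2_eyt), rng,
                                  env=state.env, year=year, stage="eyt2")
        state.archive.add(cohort, np.array([r.phenotype for r in records]),
                          year, stage="eyt2")
        # Stage 8: the variety is the best varietal mean over both elite
        # trial years; recorded, never fed back into selection.
        means = [(state.eyt1_pheno.get(ind.id, r.phenotype) + r.phenotype) / 2
                 for ind, r in zip(cohort, records)]
        best = max(range(len(cohort)), key=lambda i: (means[i], -cohort[i].id))
        variety_tbv = float(true_breeding_values([cohort[best]],
                                                 state.trait)[0])

    # Parent selection. The stage-4 pool is evaluated at the PYT; the
    # stage-5-derived pool is the cohort advanced out of the AYT, evaluated
    # on its current first-year-elite record.
    if cfg.criterion == "gebv" and len(state.archive) >= 2:
        training = build_training_set(state.archive, "allGen", year,
                                      stage_filter=TRAINING_STAGES)
        state.marker_model = fit_rrblup(training)

    def gebvs(inds: list[Individual]) -> np.ndarray:
        return predict_gebv(state.marker_model, inds)

    pool4: list[_RsayCandidate] = []
    pool5: list[_RsayCandidate] = []
    if cfg.criterion == "phenotype" or state.marker_model is None:
        if cfg.policy == "discrete":
            pool4 = [_RsayCandidate(ind, r.phenotype, r)
                     for ind, r in zip(pyt_cohort, pyt_records)]
            pool5 = [_RsayCandidate(ind, r.phenotype, r)
                     for ind, r in zip(eyt1_cohort, eyt1_records)]
        else:
            pool4 = list(state.pyt_history)
            pool5 = list(state.eyt1_history)
    else:  # GEBV criterion: refresh predictions for the whole pool
        if cfg.policy == "discrete":
            inds4, inds5 = pyt_cohort, eyt1_cohort
        else:
            inds4, inds5 = state.pyt_inds, state.eyt1_inds
        if inds4:
            pool4 = [_RsayCandidate(ind, float(v), None)
                     for ind, v in zip(inds4, gebvs(inds4))]
        if inds5:
            pool5 = [_RsayCandidate(ind, float(v), None)
                     for ind, v in zip(inds5, gebvs(inds5))]

    def top(pool: list[_RsayCandidate], n: int,
            exclude: set[int]) -> list[_RsayCandidate]:
        ranked = sorted((c for c in pool if c.individual.id not in exclude),
                        key=lambda c: (-c.value, c.individual.id))
        return ranked[:n]

    steady = bool(pool4) and bool(pool5)
    sel5 = top(pool5, cfg.n_parents_stage5, set())
    sel4 = top(pool4, cfg.n_parents_stage4,
               {c.individual.id for c in sel5})
    selected = sel4 + sel5
    candidates = pool4 + pool5
    if len(selected) < cfg.n_parents:
        # Pipeline fill: backfill parent slots from the ranked founders.
        have = {c.individual.id for c in selected}
        fill = [f for f in state.founder_ranked if f.id not in have]
        parents = [c.individual for c in selected]
        parents += fill[:cfg.n_parents - len(parents)]
    else:
        parents = [c.individual for c in selected]
    state.parents = parents

    # Metrics on this year's parents and candidate pools.
    row = {"cycle": year, "steady_state": steady, "variety_tbv": variety_tbv}
    if steady and selected:
        sel_tbv = true_breeding_values([c.individual for c in selected],
                                       state.trait)
        all_tbv = true_breeding_values([c.individual for c in candidates],
                                       state.trait)
        sel_val = np.array([c.value for c in selected])
        all_val = np.array([c.value for c in candidates])
        row["selection_error_bias"] = selection_error_bias(
            sel_val - sel_tbv, all_val - all_tbv)
        if cfg.criterion == "phenotype":
            sel_dec = ErrorDecomposition(
                total=sel_val - sel_tbv,
                year=np.array([c.record.year_effect for c in selected]),
                gxy=np.array([c.record.gxy for c in selected]),
                plot=np.array([c.record.plot_error for c in selected]))
            all_dec = ErrorDecomposition(
                total=all_val - all_tbv,
                year=np.array([c.record.year_effect for c in candidates]),
                gxy=np.array([c.record.gxy for c in candidates]),
                plot=np.array([c.record.plot_error for c in candidates]))
            by, bg, bp = decompose_error_bias(sel_dec, all_dec)
        else:
            by = bg = bp = np.nan
        row.update({"bias_year": by, "bias_gxy": bg, "bias_plot": bp,
                    "accuracy": selection_accuracy(sel_val, sel_tbv)})
    else:
        row.update({"selection_error_bias": np.nan, "bias_year": np.nan,
                    "bias_gxy": np.nan, "bias_plot": np.nan,
                    "accuracy": np.nan})
    mean_tbv, var_tbv = genetic_stats(parents, state.trait)
    row.update({
        "mean_genetic_value": mean_tbv, "genetic_variance": var_tbv,
        "inbreeding": ibd_inbreeding(parents),
        "mean_parental_age": mean_parental_age(parents, year),
        "n_candidates": len(candidates), "n_selected": len(selected)})
    state.rows.append(row)

    # Stage 1: cross this year's parents; the new cohort is born this year.
    plan = random_pair_crosses(len(parents), cfg.n_crosses,
                               cfg.progeny_per_cross, rng)
    f1_new: list[Individual] = []
    for x in plan:
        f1_new.extend(make_cross(parents[x.mother_idx], parents[x.father_idx],
                                 x.n_progeny, year, rng, cfg.genome,
                                 first_id=state.next_id))
        state.next_id += x.n_progeny
    next_stages["f1"] = f1_new

    state.stages = next_stages
    return state


def run_rsay_scenario(cfg: RsayConfig, seed: int) -> pd.DataFrame:
    """Run one RS-AY scenario for ``cfg.n_years`` years."""
    state = init_rsay(cfg, seed)
    for _ in range(cfg.n_years):
        run_rsay_year(state, cfg)
    cols = METRIC_COLUMNS + ["variety_tbv"]
    frame = pd.DataFrame(state.rows)
    return frame[[c for c in cols if c in frame.columns]]
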