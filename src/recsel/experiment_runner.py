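"""Scenario-grid expansion, seeded replicate execution, and timepoint
statistics.

The RS-A factor grid crosses generation policy (discrete/overlapping) and
heritability (0.1/0.5/0.9) with the selection criterion: phenotypic
selection at 1 or 3 replicates, true-breeding-value selection, and genomic
selection (truncation or optimum-contribution) under each training window
(allGen/fiveGen), with an effective-population-size floor per OCS level.
RS-AY has four scenarios: {discrete, overlapping} x {phenotypic, genomic}.

Scenario contrasts are Welch two-sample tests of replicate-level responses
at the chosen timepoints (with one observation per replicate per scenario
the heteroscedastic mixed-model contrast reduces to Welch's test).
Structural constants (mean parental age, year error bias) are checked with
one-sample t tests against their fixed reference values under Bonferroni
correction.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, fields, replace

import numpy as np
import pandas as pd
from scipy import stats

from .breeding_pipelines import (RsaConfig, RsayConfig, run_rsa_scenario,
                                 run_rsay_scenario)

H2_LEVELS = (0.1, 0.5, 0.9)
NE_LEVELS = (10.0, 45.0, 90.0)
RSA_TIMEPOINTS = (5, 25, 45)
RSAY_TIMEPOINTS = (40,)


@dataclass(frozen=True)
class Scenario:
    scenario_id: str
    kind: str  # rsa | rsay
    config: object  # RsaConfig | RsayConfig


@dataclass
class ExperimentPlan:
    scenarios: list[Scenario]
    n_replicates: int = 10
    base_seed: int = 1
    timepoints: tuple = RSA_TIMEPOINTS

    def __post_init__(self) -> None:
        ids = [s.scenario_id for s in self.scenarios]
        if len(set(ids)) != len(ids):
            raise ValueError("scenario ids must be unique")
        if not self.scenarios:
            raise ValueError("empty scenario list")


def _rsa_id(cfg: RsaConfig) -> str:
    parts = [f"rsa_{cfg.policy}_{cfg.criterion}_h{cfg.h2:g}"]
    if cfg.criterion == "phenotype":
        parts.append(f"rep{cfg.n_reps_phenotype}")
    if cfg.criterion == "gebv":
        parts.append(cfg.gs_mode)
        parts.append(cfg.training_window)
        if cfg.gs_mode == "ocs":
            parts.append(f"ne{cfg.min_Ne:g}")
    return "_".join(parts)


def expand_rsa_scenarios(policies=("discrete", "overlapping"),
                         h2_levels=H2_LEVELS, criteria=("phenotype", "tbv",
                                                        "gebv"),
                         rep_levels=(1, 3), gs_modes=("truncation", "ocs"),
                         training=("allGen", "fiveGen"), ne_levels=NE_LEVELS,
                         **overrides) -> list[Scenario]:
    """Full cross of applicable RS-A factors; inapplicable combinations
    (replication without phenotypes, Ne without OCS) are pruned."""
    out = []
    for policy in policies:
        for h2 in h2_levels:
            if h2 <= 0 or h2 > 1:
                raise ValueError(f"invalid heritability level {h2}")
            for crit in criteria:
                if crit not in ("phenotype", "tbv", "gebv"):
                    raise ValueError(f"unknown criterion level {crit!r}")
                if crit == "phenotype":
                    for reps in rep_levels:
                        cfg = RsaConfig(h2=h2, policy=policy, criterion=crit,
                                        n_reps_phenotype=reps, **overrides)
                        out.append(Scenario(_rsa_id(cfg), "rsa", cfg))
                elif crit == "tbv":
                    cfg = RsaConfig(h2=h2, policy=policy, criterion=crit,
                                    **overrides)
                    out.append(Scenario(_rsa_id(cfg), "rsa", cfg))
                else:
                    for mode in gs_modes:
                        for window in training:
                            if mode == "truncation":
                                cfg = RsaConfig(h2=h2, policy=policy,
                                                criterion=crit, gs_mode=mode,
                                                training_window=window,
                                                **overrides)
                                out.append(Scenario(_rsa_id(cfg), "rsa", cfg))
                            else:
                                for ne in ne_levels:
                                    cfg = RsaConfig(
                                        h2=h2, policy=policy, criterion=crit,
                                        gs_mode=mode, training_window=window,
                                        min_Ne=ne, **overrides)
                                    out.append(
                                        Scenario(_rsa_id(cfg), "rsa", cfg))
    return out


def expand_rsay_scenarios(reduced: bool = False, **overrides) -> list[Scenario]:
    """The four RS-AY scenarios: policy x criterion."""
    out = []
    for policy in ("discrete", "overlapping"):
        for crit in ("phenotype", "gebv"):
            if reduced:
                cfg = RsayConfig.reduced(policy=policy, criterion=crit,
                                         **overrides)
            else:
                cfg = RsayConfig(policy=policy, criterion=crit, **overrides)
            out.append(Scenario(f"rsay_{policy}_{crit}", "rsay", cfg))
    return out


def replicate_seed(base_seed: int, scenario_id: str, replicate: int) -> int:
    """Stable per-replicate seed: hash(base_seed, scenario_id, replicate)."""
    h = zlib.crc32(f"{base_seed}|{scenario_id}|{replicate}".encode())
    return int(h) % (2 ** 31)


def reduced_scale(plan: ExperimentPlan, n_cycles: int = 20,
                  n_replicates: int = 5,
                  timepoints: tuple | None = None) -> ExperimentPlan:
    """Shrink a plan for desk-scale runs (fewer cycles and replicates)."""
    scenarios = []
    for s in plan.scenarios:
        if s.kind == "rsa":
            cfg = replace(s.config, n_cycles=n_cycles)
        else:
            cfg = replace(s.config, n_years=n_cycles)
        scenarios.append(Scenario(s.scenario_id, s.kind, cfg))
    tp = timepoints if timepoints is not None else tuple(
        t for t in plan.timepoints if t <= n_cycles) or (n_cycles,)
    return ExperimentPlan(scenarios=scenarios, n_replicates=n_replicates,
                          base_seed=plan.base_seed, timepoints=tp)


def run_scenario_replicate(scenario: Scenario, base_seed: int,
                           replicate: int) -> pd.DataFrame:
    seed = replicate_seed(base_seed, scenario.scenario_id, replicate)
    runner = run_rsa_scenario if scenario.kind == "rsa" else run_rsay_scenario
    frame = runner(scenario.config, seed)
    frame.insert(0, "scenario_id", scenario.scenario_id)
    frame.insert(0, "replicate", replicate)
    return frame


def run_experiment(plan: ExperimentPlan, out_dir=None) -> pd.DataFrame:
    """Run every scenario x replicate; returns (and optionally writes) the
    stacked metrics table, one CSV per scenario x replicate."""
    frames = []
    for scenario in plan.scenarios:
        for rep in range(plan.n_replicates):
            frame = run_scenario_replicate(scenario, plan.base_seed, rep)
            frames.append(frame)
            if out_dir is not None:
                from pathlib import Path

                out = Path(out_dir)
                out.mkdir(parents=True, exist_ok=True)
                frame.to_csv(out / f"{scenario.scenario_id}_rep{rep}.csv",
                             index=False, float_format="%.10g")
    return pd.concat(frames, ignore_index=True)


def _policy_pairs(archive: pd.DataFrame) -> list[tuple[str, str]]:
    ids = sorted(archive["scenario_id"].unique())
    pairs = []
    for sid in ids:
        if "_discrete_" in sid:
            partner = sid.replace("_discrete_", "_overlapping_")
            if partner in ids:
                pairs.append((sid, partner))
    return pairs


def timepoint_contrasts(archive: pd.DataFrame, response: str,
                        timepoint: int, alternative: str = "two-sided"
                        ) -> pd.DataFrame:
    """Discrete-vs-overlapping Welch contrasts at one timepoint.

    One row per matched scenario pair: estimate (discrete minus
    overlapping), 95% CI, Welch p. Pairs missing the timepoint (e.g. a
    scenario truncated by OCS infeasibility) are flagged unavailable.
    """
    rows = []
    for disc_id, over_id in _policy_pairs(archive):
        row = {"discrete": disc_id, "overlapping": over_id,
               "timepoint": timepoint, "available": False,
               "estimate": np.nan, "ci_low": np.nan, "ci_high": np.nan,
               "p": np.nan}
        a = archive[(archive.scenario_id == disc_id)
                    & (archive.cycle == timepoint)][response].dropna()
        b = archive[(archive.scenario_id == over_id)
                    & (archive.cycle == timepoint)][response].dropna()
        if len(a) >= 2 and len(b) >= 2:
            est = float(a.mean() - b.mean())
            se = float(np.sqrt(a.var(ddof=1) / len(a) + b.var(ddof=1) / len(b)))
            if se == 0.0:
                # Structurally constant responses: an exact tie is p = 1,
                # an exact difference is p = 0.
                p = 1.0 if est == 0.0 else 0.0
                tcrit = 0.0
            else:
                res = stats.ttest_ind(a, b, equal_var=False,
                                      alternative=alternative)
                p = float(res.pvalue)
                tcrit = float(stats.t.ppf(0.975, res.df))
            row.update({"available": True, "estimate": est,
                        "ci_low": est - tcrit * se, "ci_high": est + tcrit * se,
                        "p": p})
        rows.append(row)
    return pd.DataFrame(rows)


def one_sample_tests(archive: pd.DataFrame, response: str, mu0: float,
                     family_size: int, timepoints: tuple) -> pd.DataFrame:
    """One-sample t tests of replicate values against a fixed mean.

    p values are Bonferroni-multiplied by ``family_size`` and capped at 1.
    Zero-variance samples: p = 1 when the mean equals mu0 exactly, else the
    exact (deterministic) difference is flagged.
    """
    rows = []
    for sid in sorted(archive["scenario_id"].unique()):
        for tp in timepoints:
            vals = archive[(archive.scenario_id == sid)
                           & (archive.cycle == tp)][response].dropna()
            row = {"scenario_id": sid, "timepoint": tp, "mu0": mu0,
                   "n": len(vals), "mean": np.nan, "p": np.nan,
                   "p_bonferroni": np.nan, "exact_difference": False}
            if len(vals) >= 2:
                row["mean"] = float(vals.mean())
                if vals.max() == vals.min():  # structurally constant
                    if abs(row["mean"] - mu0) < 1e-12:
                        row["p"] = 1.0
                    else:
                        row["exact_difference"] = True
                else:
                    row["p"] = float(stats.ttest_1samp(vals, mu0).pvalue)
                if row["p"] is not None and not np.isnan(row["p"]):
                    row["p_bonferroni"] = min(1.0, row["p"] * family_size)
            rows.append(row)
    return pd.DataFrame(rows)


def plan_manifest(plan: ExperimentPlan) -> pd.DataFrame:
    """Seed ledger: every (scenario, replicate) with its derived seed."""
    rows = []
    for s in plan.scenarios:
        cfg = {f.name: getattr(s.config, f.name) for f in fields(s.config)
               if f.name != "genome"}
        for rep in range(plan.n_replicates):
            rows.append({"scenario_id": s.scenario_id, "kind": s.kind,
                         "replicate": rep,
                         "seed": replicate_seed(plan.base_seed,
                                                s.scenario_id, rep),
                         **cfg})
    return pd.DataFrame(rows)
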