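"""Quantitative trait model: additive QTL effects, year and genotype-by-year
effects, plot errors, and phenotype assembly.

The trait is purely additive at the QTL level. Effects are drawn N(0, 1) and
rescaled by a single scalar so the founder-population variance of true
breeding values (TBVs) equals the target base genetic variance (1 by
default); an intercept centers the founder mean TBV at 0.

For the multi-stage pipeline the phenotype follows a compound-symmetry
genotype-by-environment model: uniform genetic variances and covariances
across years. Each year contributes a common year effect ~ N(0, 0.2) and a
year-specific additive deviation per QTL drawn with variance
sigma_a^2 * sigma_ay^2 / sigma_G^2, which calibrates the realized
genotype-by-year variance across individuals to sigma_ay^2 (0.2 by default).
Plot errors are tuned per trial stage to hit the stage's target
heritability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .founder_genomes import FounderPopulation, GenomeSpec, Individual


@dataclass
class TraitModel:
    """Additive QTL effects plus the scaling bookkeeping.

    ``qtl_sites`` has shape (n_chromosomes, qtl_per_chromosome) holding site
    indices; ``effects`` is the flat per-QTL additive effect vector in the
    same chromosome-major order.
    """

    qtl_sites: np.ndarray
    effects: np.ndarray
    intercept: float
    base_genetic_variance: float
    spec: GenomeSpec

    @property
    def effect_variance(self) -> float:
        """Variance of the additive QTL effects (sigma_a^2)."""
        return float(np.var(self.effects))


@dataclass
class HeritabilitySpec:
    """Target heritability for a phenotyping event.

    ``kind`` is "narrow" (h2: single-cohort mass selection) or "broad"
    (H2: stage-level trial precision in the multi-stage pipeline). The error
    variance implied by either kind is sigma_G^2 (1 - value) / value,
    divided by the replicate count.
    """

    value: float
    kind: str = "narrow"
    n_reps: int = 1

    def __post_init__(self) -> None:
        if not (0.0 < self.value <= 1.0):
            raise ValueError("heritability must be in (0, 1]")
        if self.n_reps < 1:
            raise ValueError("replicate count must be >= 1")
        if self.kind not in ("narrow", "broad"):
            raise ValueError("kind must be 'narrow' or 'broad'")


@dataclass
class PhenotypeRecord:
    """One phenotyping event with its exact component decomposition."""

    id: int
    phenotype: float
    tbv: float
    year_effect: float
    gxy: float
    plot_error: float
    year: int = 0
    stage: str = ""
    n_reps: int = 1


@dataclass
class EnvironmentModel:
    """Year and genotype-by-year effect store for the compound-symmetry model.

    Effects are sampled lazily per year from seeds derived from
    (base_seed, year), so the same year always returns the identical values
    regardless of query order.
    """

    year_effect_variance: float = 0.2
    gxy_target_variance: float = 0.2
    base_seed: int = 0
    _year_effects: dict = field(default_factory=dict, repr=False)
    _gxy_effects: dict = field(default_factory=dict, repr=False)

    def year_effect(self, year: int) -> float:
        if year not in self._year_effects:
            rng = np.random.default_rng([self.base_seed, 7, year])
            self._year_effects[year] = float(
                rng.normal(0.0, np.sqrt(self.year_effect_variance)))
        return self._year_effects[year]

    def gxy_effects(self, trait: TraitModel, year: int) -> np.ndarray:
        """Per-QTL additive deviations for one year.

        Drawn N(0, sigma_a^2 * sigma_ay^2 / sigma_G^2), independent across
        years and cached per year.
        """
        if year not in self._gxy_effects:
            var = (trait.effect_variance * self.gxy_target_variance
                   / trait.base_genetic_variance)
            rng = np.random.default_rng([self.base_seed, 11, year])
            self._gxy_effects[year] = rng.normal(
                0.0, np.sqrt(var), size=trait.effects.shape)
        return self._gxy_effects[year]


def sample_site_roles(spec: GenomeSpec,
                      rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Sample disjoint QTL and chip site indices per chromosome.

    The same chip sites are genotyped every cycle; QTL sites carry the
    additive effects; all remaining sites are neutral and ungenotyped.
    """
    qtl = np.empty((spec.n_chromosomes, spec.qtl_per_chromosome), dtype=np.int64)
    chip = np.empty((spec.n_chromosomes, spec.chip_sites_per_chromosome),
                    dtype=np.int64)
    k = spec.qtl_per_chromosome + spec.chip_sites_per_chromosome
    for c in range(spec.n_chromosomes):
        picked = rng.choice(spec.sites_per_chromosome, size=k, replace=False)
        qtl[c] = np.sort(picked[:spec.qtl_per_chromosome])
        chip[c] = np.sort(picked[spec.qtl_per_chromosome:])
    return qtl, chip


def site_dosages(individuals: list[Individual], sites: np.ndarray) -> np.ndarray:
    """Dosage matrix (n_individuals, n_sites_selected) at the given sites.

    ``sites`` is (n_chromosomes, k); output columns are chromosome-major.
    """
    n_chr, k = sites.shape
    out = np.empty((len(individuals), n_chr * k))
    for i, ind in enumerate(individuals):
        dose = ind.haplotypes.sum(axis=1)  # (n_chr, m)
        out[i] = dose[np.arange(n_chr)[:, None], sites].reshape(-1)
    return out


def assign_qtl_effects(founders: FounderPopulation, qtl_sites: np.ndarray,
                       target_variance: float, seed: int) -> TraitModel:
    """Draw additive QTL effects and scale to the target founder TBV variance.

    Raw effects are N(0, 1); a single scalar multiplies them so the sample
    variance (ddof=1) of TBVs over the founders equals ``target_variance``
    exactly, and the intercept centers the founder mean TBV at 0.
    """
    rng = np.random.default_rng(seed)
    raw = rng.standard_normal(qtl_sites.size)
    D = site_dosages(founders.individuals, qtl_sites)
    tbv_raw = D @ raw
    v = float(np.var(tbv_raw, ddof=1))
    if v <= 0.0:
        raise ValueError("degenerate founder population: zero TBV variance")
    effects = raw * np.sqrt(target_variance / v)
    intercept = -float(np.mean(D @ effects))
    return TraitModel(qtl_sites=qtl_sites, effects=effects, intercept=intercept,
                      base_genetic_variance=target_variance, spec=founders.spec)


def true_breeding_value(individual: Individual, trait: TraitModel) -> float:
    dose = individual.haplotypes.sum(axis=1)
    n_chr = trait.qtl_sites.shape[0]
    if dose.shape[0] != n_chr:
        raise ValueError("genome does not match trait QTL layout")
    d = dose[np.arange(n_chr)[:, None], trait.qtl_sites].reshape(-1)
    return float(trait.intercept + d @ trait.effects)


def true_breeding_values(individuals: list[Individual],
                         trait: TraitModel) -> np.ndarray:
    D = site_dosages(individuals, trait.qtl_sites)
    return trait.intercept + D @ trait.effects


def error_variance_for_h2(h2: float, genetic_variance: float,
                          n_reps: int = 1) -> float:
    """Plot-error variance hitting a target heritability.

    sigma_G^2 (1 - h2) / h2, divided by the replicate count (replicated
    phenotypes are means over replicates).
    """
    if not (0.0 < h2 <= 1.0):
        raise ValueError("heritability must be in (0, 1]")
    return genetic_variance * (1.0 - h2) / h2 / n_reps


def gxy_deviations(individuals: list[Individual], trait: TraitModel,
                   env: EnvironmentModel, year: int) -> np.ndarray:
    """Per-individual genotype-by-year deviations for one year."""
    g = env.gxy_effects(trait, year)
    D = site_dosages(individuals, trait.qtl_sites)
    return D @ g


def make_phenotypes(individuals: list[Individual], trait: TraitModel,
                    herit: HeritabilitySpec, rng: np.random.Generator,
                    env: EnvironmentModel | None = None, year: int = 0,
                    stage: str = "") -> list[PhenotypeRecord]:
    """Phenotype a cohort.

    Without an ``EnvironmentModel`` (single-cohort mass selection) the
    phenotype is TBV + plot error at the target narrow-sense heritability.
    With one (multi-stage pipeline), phenotype = TBV + year effect +
    genotype-by-year deviation + plot error; every component is stored on
    the record so selection error can be decomposed exactly.
    """
    if herit.kind == "broad" and env is None:
        raise ValueError("broad-sense phenotyping requires an EnvironmentModel")
    tbvs = true_breeding_values(individuals, trait)
    err_sd = np.sqrt(error_variance_for_h2(
        herit.value, trait.base_genetic_variance, herit.n_reps))
    plot = rng.normal(0.0, err_sd, size=len(individuals))
    if env is None:
        year_eff = 0.0
        gxy = np.zeros(len(individuals))
    else:
        year_eff = env.year_effect(year)
        gxy = gxy_deviations(individuals, trait, env, year)
    return [
        PhenotypeRecord(
            id=ind.id,
            phenotype=float(tbvs[i] + year_eff + gxy[i] + plot[i]),
            tbv=float(tbvs[i]), year_effect=float(year_eff), gxy=float(gxy[i]),
            plot_error=float(plot[i]), year=year, stage=stage,
            n_reps=herit.n_reps)
        for i, ind in enumerate(individuals)
    ]


def records_to_frame(records: list[PhenotypeRecord]):
    """Serialize phenotype records to a pandas DataFrame (CSV-ready)."""
    import pandas as pd

    return pd.DataFrame(
        [{"id": r.id, "year": r.year, "stage": r.stage, "reps": r.n_reps,
          "phenotype": r.phenotype, "tbv": r.tbv, "year_effect": r.year_effect,
          "gxy": r.gxy, "plot_error": r.plot_error} for r in records])
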