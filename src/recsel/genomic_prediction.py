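"""RR-BLUP genomic prediction on chip genotypes.

Fits y = 1*mu + Z m + e with m ~ N(0, I sigma_m^2), e ~ N(0, I sigma_e^2)
on column-centered 0/1/2 chip dosages. The variance ratio
delta = sigma_e^2 / sigma_m^2 is estimated by restricted maximum likelihood:
because the centered dosage matrix is orthogonal to the intercept, the
restricted likelihood profiles to a one-dimensional function of delta over
the singular values of the centered matrix, maximized by bounded scalar
search. A fixed ratio can be supplied instead (e.g. derived from a known
heritability), which is cheaper and exactly reproduces the
GBLUP-equivalent solution.

Training sets are assembled from a phenotype archive under two window
policies: every phenotyped record to date ("allGen"), or the five most
recent previous cycles plus the current one ("fiveGen"); the multi-stage
pipeline additionally restricts training to yield-trial stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

from .founder_genomes import Individual
from .trait_architecture import site_dosages

_RIDGE_EPS = 1e-10


@dataclass
class PhenotypeArchive:
    """Append-only store of phenotyped records with their chip genotypes."""

    chip_sites: np.ndarray
    dosages: list = field(default_factory=list)
    phenotypes: list = field(default_factory=list)
    cycles: list = field(default_factory=list)
    stages: list = field(default_factory=list)
    ids: list = field(default_factory=list)

    def add(self, individuals: list[Individual], phenotypes: np.ndarray,
            cycle: int, stage: str = "") -> None:
        D = site_dosages(individuals, self.chip_sites)
        for i, ind in enumerate(individuals):
            self.dosages.append(D[i])
            self.phenotypes.append(float(phenotypes[i]))
            self.cycles.append(cycle)
            self.stages.append(stage)
            self.ids.append(ind.id)

    def __len__(self) -> int:
        return len(self.phenotypes)


@dataclass
class TrainingSet:
    X: np.ndarray  # (n_records, n_chip_sites) dosages
    y: np.ndarray
    cycles: np.ndarray
    stages: list
    chip_sites: np.ndarray

    def __post_init__(self) -> None:
        if self.X.ndim != 2 or self.X.shape[0] != self.y.shape[0]:
            raise ValueError("dosage matrix and phenotypes are inconsistent")


@dataclass
class MarkerModel:
    """Fitted RR-BLUP: chip-site effects, intercept and variance components."""

    marker_effects: np.ndarray
    intercept: float
    variance_ratio: float  # sigma_e^2 / sigma_m^2
    column_means: np.ndarray
    chip_sites: np.ndarray
    sigma_m2: float = float("nan")
    sigma_e2: float = float("nan")


def build_training_set(archive: PhenotypeArchive, mode: str, current_cycle: int,
                       stage_filter: set[str] | None = None) -> TrainingSet:
    """Select archive records for model training.

    ``allGen`` keeps every record to date; ``fiveGen`` keeps records from the
    five most recent previous cycles plus the current cycle's own records.
    ``stage_filter`` restricts to the named stages (yield-trial training in
    the multi-stage pipeline).
    """
    if mode not in ("allGen", "fiveGen"):
        raise ValueError(f"unknown training mode: {mode!r}")
    cyc = np.asarray(archive.cycles)
    mask = cyc <= current_cycle
    if mode == "fiveGen":
        mask &= cyc >= current_cycle - 5
    if stage_filter is not None:
        stage_ok = np.array([s in stage_filter for s in archive.stages])
        mask &= stage_ok
    if not mask.any():
        raise ValueError(
            f"empty training set (mode={mode}, cycle={current_cycle}, "
            f"stages={stage_filter})")
    idx = np.flatnonzero(mask)
    return TrainingSet(
        X=np.asarray([archive.dosages[i] for i in idx], dtype=float),
        y=np.asarray([archive.phenotypes[i] for i in idx], dtype=float),
        cycles=cyc[idx],
        stages=[archive.stages[i] for i in idx],
        chip_sites=archive.chip_sites)


def _reml_ratio(d: np.ndarray, y_tilde: np.ndarray, sse_perp: float,
                n: int) -> float:
    """Profile-REML estimate of delta = sigma_e^2/sigma_m^2 on log scale.

    ``d``: nonzero eigenvalues of Xc Xc'; ``y_tilde``: phenotype projections
    onto the corresponding eigenvectors; ``sse_perp``: residual sum of
    squares orthogonal to the marker span and the intercept.
    """
    r = d.size

    def neg_restricted_ll(log_delta: float) -> float:
        delta = np.exp(log_delta)
        q = float(np.sum(y_tilde ** 2 / (d + delta)))
        if n - 1 > r:
            q += sse_perp / delta
        sigma2 = q / (n - 1)
        val = ((n - 1) * np.log(max(sigma2, 1e-300))
               + float(np.sum(np.log(d + delta)))
               + (n - 1 - r) * np.log(delta))
        return val

    res = minimize_scalar(neg_restricted_ll, bounds=(-12.0, 12.0),
                          method="bounded", options={"xatol": 1e-6})
    return float(np.exp(res.x))


def fit_rrblup(training: TrainingSet,
               variance_ratio: float | None = None) -> MarkerModel:
    """Fit RR-BLUP marker effects; deterministic given inputs.

    Monomorphic chip columns center to zero and therefore receive exactly
    zero effect. Constant phenotypes short-circuit to an all-zero effect
    vector with the common value as intercept.
    """
    X, y = training.X, training.y
    n = len(y)
    if n < 2:
        raise ValueError("need at least 2 training records")
    col_means = X.mean(axis=0)
    Xc = X - col_means
    if float(np.var(y)) == 0.0:
        return MarkerModel(
            marker_effects=np.zeros(X.shape[1]), intercept=float(y[0]),
            variance_ratio=np.inf, column_means=col_means,
            chip_sites=training.chip_sites, sigma_m2=0.0, sigma_e2=0.0)
    if not np.any(np.abs(Xc) > 0):
        raise ValueError("no polymorphic chip site in the training set")

    # Columns are centered, so Xc'1 = 0: the intercept GLS estimate is the
    # plain mean and the restricted likelihood separates over the SVD of Xc.
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    keep = s > max(s[0], 1.0) * 1e-12
    U, s, Vt = U[:, keep], s[keep], Vt[keep]
    d = s ** 2
    ybar = float(np.mean(y))
    yc = y - ybar
    y_tilde = U.T @ yc
    sse_perp = max(float(yc @ yc - y_tilde @ y_tilde), 0.0)

    if variance_ratio is None:
        delta = _reml_ratio(d, y_tilde, sse_perp, n)
    else:
        if variance_ratio <= 0:
            raise ValueError("variance ratio must be positive")
        delta = float(variance_ratio)

    coef = (s / (d + delta)) * y_tilde
    effects = Vt.T @ coef
    q = float(np.sum(y_tilde ** 2 / (d + delta))) + (
        sse_perp / delta if n - 1 > d.size else 0.0)
    sigma_m2 = q / (n - 1)
    return MarkerModel(
        marker_effects=effects, intercept=ybar, variance_ratio=delta,
        column_means=col_means, chip_sites=training.chip_sites,
        sigma_m2=sigma_m2, sigma_e2=delta * sigma_m2)


def predict_gebv(model: MarkerModel,
                 individuals: list[Individual]) -> np.ndarray:
    """GEBV = intercept + centered chip dosages @ marker effects.

    Candidates from any cycle are re-scored with the current model; this
    refresh is what lets overlapping-generation genomic selection revise
    old candidates' estimates without new phenotypes.
    """
    D = site_dosages(individuals, model.chip_sites)
    if D.shape[1] != model.marker_effects.shape[0]:
        raise ValueError("chip layout does not match the fitted model")
    return model.intercept + (D - model.column_means) @ model.marker_effects


def predict_gebv_dosages(model: MarkerModel, dosages: np.ndarray) -> np.ndarray:
    return model.intercept + (dosages - model.column_means) @ model.marker_effects
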