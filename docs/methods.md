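# Methods

This note documents the models, calibrations, numerical choices and known
limitations of `recsel`. Everything stated here is computed by the code; the
test suite and `scripts/acceptance.py` exercise each claim.

## Genomes and founders

Individuals are diploid with 10 chromosomes of 1000 biallelic segregating
sites (configurable through `GenomeSpec`). The genetic map is 1.0 Morgan
per chromosome with uniform site spacing; meiosis draws a Poisson(map
length) crossover count with breakpoints uniform on the map and no
interference, and a map length of 0 degenerates to intact transmission.
These are the standard defaults of forward breeding-program simulators;
the source study does not state map lengths or interference, so they are
package choices.

Founders are not produced by a coalescent. Instead, 20 ancestral
haplotypes are drawn with per-site allele frequencies from Beta(0.5, 0.5)
(a U-shaped site-frequency spectrum), and each of the 2N founder
haplotypes is a Markov mosaic of ancestral segments with a switch rate of
one per Morgan. The mosaic induces block-wise linkage disequilibrium (LD)
that decays with map distance, which is the property the downstream
analyses need; it does not reproduce any particular demographic history.
Sites monomorphic in the realized founder sample are resampled (new
ancestral column) so every site segregates at generation 0. All
comparisons the package is designed for are *relative* contrasts between
selection policies sharing the same founder process, so the founder model
only needs to be plausible, not historically calibrated. A coalescent
generator can be substituted by building the same `FounderPopulation`
container from other haplotypes.

### Identity by descent

Every founder haplotype carries a unique integer label per chromosome.
Labels are copied, never mutated, through every meiosis, so descent is
tracked exactly. Coancestry of two individuals is the probability that
one allele drawn from each at a uniformly random site shares a label;
population inbreeding is the mean over unordered pairs of distinct
individuals; the OCS kinship matrix additionally uses self-kinship
(1 + F)/2 on the diagonal. These are exact computations on labels, not
marker estimates. A pedigree-based tabular-method kinship is included as
an independent oracle for tests (full sibs: 1/4).

## Trait model

The trait is strictly additive: 100 QTL per chromosome, sampled uniformly
and disjointly from the 50 chip sites per chromosome (the same chip sites
are genotyped every cycle; all other sites are neutral). Raw effects are
N(0, 1), then multiplied by one scalar so the founder sample variance
(ddof = 1) of TBVs equals the base genetic variance σ²_G = 1 exactly; the
intercept centers the founder mean TBV at 0. The ddof = 1 convention was
chosen so the calibration is exact under the same estimator used to
measure it.

Phenotypes in the single-cohort program are TBV + plot error with error
variance σ²_G(1 − h²)/h² divided by the replicate count (replicated
phenotypes are plot means), giving narrow-sense heritabilities of exactly
h² ∈ {0.1, 0.5, 0.9} in the base population. Error variances are frozen
at base-population values across cycles; they are not re-tuned as genetic
variance erodes, so realized heritability drifts downward over cycles by
design.

### Year and genotype-by-year effects (compound symmetry)

The multi-stage pipeline adds a common year effect ~ N(0, 0.2) shared by
every plot grown in that year, a year-specific additive deviation per QTL,
and stage-specific plot error. Per-QTL year deviations are drawn
N(0, σ²ₐ·σ²ₐy/σ²_G), where σ²ₐ is the variance of the (scaled) additive
QTL effects and σ²ₐy = 0.2 is the target genotype-by-year variance. This
is a compound-symmetry model: the genetic covariance of one genotype's
phenotypes across any two years is σ²_G, uniformly.

One calibration subtlety is worth stating plainly: the additive scaling
divides by the *realized* founder TBV variance, which contains an
LD-dependent quadratic-form term that fluctuates roughly ±20% across
trait draws. Consequently a single trait's realized G×Y variance is
0.2·(σ²ₐ·trΣ/σ²_G), where Σ is the founder dosage covariance at the QTL —
on average 0.2, but not for any one trait. All checks of the 0.2 target
therefore average over independent trait replicates as well as years;
`scripts/acceptance.py` uses 24 trait draws × 12 years.

Stage heritabilities H² ∈ {0.1, 0.2, 0.5, 0.8} set the plot-error
variance per trial stage as σ²_G(1 − H²)/H² with σ²_G the base genetic
variance, *excluding* the year variance (common to every entry in a
trial, hence irrelevant to within-trial ranking) and excluding the G×Y
variance from the denominator. Whether stage-level H² should include the
G×Y variance is genuinely open; the chosen anchoring to base genetic
variance is the convention of mainstream breeding simulators, and the
alternative only rescales plot error by a factor (1 + σ²ₐy/σ²_G) · H²
adjustments without affecting policy contrasts.

## Genomic prediction

RR-BLUP fits y = 1μ + Zm + e on column-centered 0/1/2 chip dosages with
m ~ N(0, Iσ²ₘ). Because centering makes Z orthogonal to the intercept,
the restricted likelihood profiles to a one-dimensional function of
δ = σ²ₑ/σ²ₘ over the singular values of the centered matrix; it is
maximized by bounded scalar search on log δ ∈ [−12, 12] with tolerance
1e−6. Monomorphic chip columns center to zero and receive exactly zero
effect; constant phenotypes short-circuit to a zero model. The fit is
deterministic and invariant to record order and to phenotype shifts
(intercept only). A fixed-δ mode bypasses REML; in that mode the fit is
verified against two independent oracles — GBLUP on the relationship
Z_cZ_c' and Henderson's mixed-model equations — to 1e−8.

Training windows: `allGen` uses every phenotyped record to date;
`fiveGen` uses the five most recent previous cycles plus the current
cycle's own records (the window-semantics choice is documented and
configurable in spirit; candidates' own unreplicated records are
included). The multi-stage pipeline trains on yield-trial stages only
(PYT, AYT, both elite years) from all cycles.

## Selection

*Truncation* takes the n largest criterion values, ties broken by
smallest id (deterministic).

*Optimum contribution selection* solves: maximize c'g subject to
c'Kc ≤ θ, c ≥ 0, Σc = 1, with K the IBD coancestry matrix and
θ = k̄ + (1 − k̄)·ΔF, ΔF = 1/(2Nₑ). The convex program is solved with
SLSQP (feasibility pre-check by minimizing c'Kc on the simplex; multiple
deterministic starts; a second pass minimizes c'Kc among solutions within
1e−8 of the optimum so degenerate merit ties resolve to the
minimum-coancestry point). The solver is validated against an exhaustive
simplex-grid search. The number of OCS parents is emergent (candidates
with c > 1e−6), not fixed.

Two θ conventions are provided. The default re-measures k̄ on the current
candidate pool each cycle; under this convention the uniform vector is
always feasible, so OCS always solves. The `scheduled` mode advances θ
along the recursion θ_t = θ_{t−1} + (1 − θ_{t−1})ΔF from the base
population — the classical target-path formulation — under which realized
coancestry can outrun the bound and the solver raises a feasibility error
carrying the minimum achievable kinship; long tightly-constrained runs
then truncate, which is the empirically observed failure mode of such
programs.

Contributions convert to a crossing plan by sampling, per cross, two
distinct parents with probability proportional to c (the second from the
renormalized remainder). Selfing is disabled throughout: the species is
modeled as hermaphroditic but crossing blocks are outcrossing.

## Program architectures

**RS-A** (single cohort). Cycle 0 phenotypes 100 founders and selects 20
parents on phenotype (in every scenario; the founders enter later
candidate pools carrying the scenario's own criterion). Each cycle: 100
random biparental crosses of the selected parents, one progeny each;
phenotype the cohort (always, so the training archive grows even under
GEBV selection); refresh GEBVs for the entire pool under genomic
selection; form the candidate pool (discrete: current cohort;
overlapping: every cohort ever evaluated, with frozen phenotypes but
refreshed GEBVs); select 20 parents by truncation, or contributions by
OCS. Metrics are recorded per cycle: genetic mean/variance on the current
cohort, error bias/accuracy/inbreeding/age on the selected parents.

**RS-AY** (multi-stage DH pipeline). Each stage takes one year. Stage 1
crosses 30 parents into 100 biparental families of 97; stage 2 doubles
each progeny to a DH line; stages 3–7 phenotype headrows (H² = 0.1,
advance 500), PYT (0.2, advance 50), AYT (0.5, advance 10), and two
elite-trial years (0.8); stage 8 records a variety (best varietal mean
over the two elite years) without feeding back into selection. Parents
are the top 20 of the current PYT cohort plus the 10 individuals advanced
out of the AYT — i.e. the current first-elite-year cohort — each ranked
on its *current-year* record (phenotype or GEBV). Because every candidate
then shares the current year effect, the year component of selection
error bias is exactly 1 under discrete generations, and the mean parental
age is exactly (20·3 + 10·5)/30 = 3.67 years, where age is the
generation interval: the offspring cohort's cross year minus the
parent's own cross year (a DH inherits its source's cross year). Under
the same definition the single-cohort discrete program gives exactly 1.
Overlapping generations draw the top 20 / top 10 from all PYT /
first-elite-year records ever; an individual qualifying through both
routes is counted once (elite slots fill first).

Pipeline fill: years 1–5 select parents from the founders' one-time
phenotypes (H² = 0.2), with partial application of the rule as stages
populate; these years are flagged `steady_state = False` and excluded
from structural-constant checks and contrasts.

## Experiment runner and statistics

The factor grid expands to 66 RS-A scenarios (2 policies × 3 h² × [2
phenotypic replication levels + TBV + 2 genomic-truncation training
windows + 2 × 3 OCS window/Nₑ combinations]) and 4 RS-AY scenarios.
Replicate seeds are CRC32 hashes of (base seed, scenario id, replicate),
recorded in a manifest; identical plans re-run byte-identically.

Scenario contrasts use Welch two-sample t tests on replicate-level
responses at fixed timepoints (cycles 5/25/45; year 40). With one
observation per replicate per scenario this is the exact reduction of a
heteroscedastic two-group mixed-model contrast; the full nested
mixed-model machinery of the original analysis is deliberately not
reproduced. Structural constants are tested with one-sample t tests
against their reference values, Bonferroni-corrected by an explicit
family size; zero-variance samples short-circuit (p = 1 on an exact tie,
an `exact_difference` flag otherwise). Bias ratios of the form 0/0 (TBV
selection, where every error is zero) are reported as NaN rather than 1,
preserving "error is zero" without inventing a ratio.

## Problem sizes used in the shipped checks

Desk-scale runs keep the full 10 × 1000 genome but shrink cohorts and
horizons: the headline directional check uses h² = 0.1, 100
candidates/cycle, 20 parents, 20 cycles, 8 seeds per policy × criterion;
the reduced RS-AY preset uses 15 crosses × 8 progeny with 60/20/5
advancement and 10 + 5 parents (the 2:1 parent-source ratio preserves the
3.67 structural constant) over 10–15 years. These sizes were chosen so
the full suite completes on a single CPU in a few minutes while leaving
the directional contrasts overwhelmingly powered (the phenotypic
discrete-vs-overlapping gap at cycle 20 is several replicate standard
deviations wide).

## Limitations

* The founder process is a stylized mosaic, not a fitted demographic
  model; absolute rates of inbreeding and LD decay should not be read as
  species estimates.
* The trait is purely additive (no dominance or epistasis), and G×E is
  compound-symmetric; regression-on-environment-mean (Finlay–Wilkinson)
  dynamics are out of scope.
* OCS mate allocation is random given contributions; no look-ahead or
  mate-selection optimization.
* GEBV selection error is recorded against the current model's
  predictions (refreshed each cycle); component decomposition of error is
  defined only for phenotypic criteria.
* Full-scale RS-AY (9700 DH/year for 40 years) is supported by the code
  but memory- and time-hungry; the reduced preset is the tested
  configuration.
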