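# recsel

Stochastic simulation of recurrent selection breeding programs with
**discrete** versus **overlapping** generations.

## The problem

Recurrent selection improves a quantitative trait by cyclically selecting
the best individuals and intermating them. Conventionally generations are
*discrete*: a candidate is evaluated once and either becomes a parent that
cycle or is discarded. If generations *overlap*, every past candidate stays
eligible — attractive, because under genomic selection old candidates can be
re-scored for free as the prediction model improves.

The catch is **selection error bias**. When selection truncates a noisy
criterion (a phenotype at low heritability, say), the selected upper tail is
enriched for individuals whose records *overstate* their true breeding value
(TBV). Bias is measured as

    b = mean |criterion − TBV| in selected parents
        ───────────────────────────────────────────
        mean |criterion − TBV| in all candidates

and b > 1 means selection chose inflated records. Discrete generations
discard those records after one cycle; overlapping generations keep
re-selecting them, so the error compounds and genetic gain suffers.
Re-estimated criteria (GEBVs from RR-BLUP, refitted each cycle) shrink old
records back toward the truth and remove the penalty.

`recsel` is for quantitative geneticists and breeding-program designers who
want to simulate these dynamics: it provides exact identity-by-descent (IBD)
tracking from founder haplotypes, an additive QTL trait scaled to unit base
variance, a compound-symmetry genotype-by-year model, RR-BLUP with REML
variance components, truncation and optimum-contribution selection (OCS,
maximize c'g subject to c'Kc ≤ θ on the simplex with θ set by a minimum
effective population size, ΔF = 1/(2Nₑ)), and two program architectures:

* **RS-A** — single-cohort recurrent mass selection: 100 founders, 100
  crosses/cycle, 20 parents, criterion ∈ {phenotype, TBV, GEBV}, h² ∈
  {0.1, 0.5, 0.9}, 50 cycles.
* **RS-AY** — a multi-stage doubled-haploid pipeline: 30 parents → 100
  crosses × 97 DH progeny → headrows (H² = 0.1) → preliminary yield trial
  (0.2) → advanced yield trial (0.5) → two elite-trial years (0.8), with
  year effects ~ N(0, 0.2) and additive-by-year effects scaled by
  σ²ₐ·σ²ₐy/σ²_G, 40 years.

Every response the study design tracks is recorded per cycle: genetic mean
and variance, selection error bias (with year/G×Y/plot decomposition in the
pipeline), IBD genomic inbreeding, selection accuracy, mean parental age.

## Worked example

Ten cycles of unreplicated phenotypic mass selection at h² = 0.1 with
overlapping generations:

```python
from recsel import RsaConfig, run_rsa_scenario

cfg = RsaConfig(h2=0.1, policy="overlapping", criterion="phenotype",
                n_cycles=10)
frame = run_rsa_scenario(cfg, seed=1)
print(frame[["cycle", "mean_genetic_value", "selection_error_bias",
             "inbreeding", "mean_parental_age"]].round(3).to_string(index=False))
```

```
 cycle  mean_genetic_value  selection_error_bias  inbreeding  mean_parental_age
     1               0.629                 2.292       0.021              1.000
     2               0.747                 2.355       0.044              1.440
     3               1.537                 2.576       0.060              1.770
     4               1.688                 2.523       0.077              2.060
     5               1.945                 2.664       0.086              2.235
     6               1.748                 2.699       0.088              3.070
     7               2.046                 2.783       0.091              3.615
     8               2.044                 2.770       0.102              3.975
     9               2.587                 2.800       0.112              4.135
    10               2.552                 2.753       0.114              4.595
```

Reading the columns: the genetic mean climbs, but the selection
error bias sits near 2.7 — the selected parents carry almost three times
the average absolute phenotype error — and the mean parental age drifts to
4.6 cycles as old, over-rated candidates are re-selected. Running the same
configuration with `policy="discrete"` holds parental age at exactly 1.0
and reaches a substantially higher genetic mean by cycle 20.

The same machinery drives the factor-grid runner and its CLI:

```sh
recsel plan --config grid.yaml --seed 1 --out manifest.csv
recsel run  --config grid.yaml --seed 1 --scale reduced --out runs/
recsel analyze --archive runs/all_metrics.csv \
    --response mean_genetic_value --timepoint 20 --out contrasts.csv
```

`analyze` performs Welch contrasts of discrete vs. overlapping variants of
otherwise-identical scenarios, or one-sample t tests against a reference
constant (`--mu0`, Bonferroni-corrected with `--family-size`).

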