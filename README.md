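# nampower

Simulation and analysis toolkit for **nested association mapping (NAM)** in
rapeseed-like genomes: it simulates founder panels and multi-parent mapping
populations, attaches quantitative traits with controllable architectures,
maps QTL jointly across all subpopulations with four linear models, and
estimates the **power of QTL detection 1−β\*** at fixed *empirical*
type-I-error rates α\*.

## Who this is for

Breeders and quantitative geneticists designing NAM experiments — choosing
between doubled-haploid (DH-NAM), backcross (BC-NAM, BC₁S₂ by single seed
descent) and recombinant-inbred (RIL-NAM, F₅) mating designs, and between
statistical models for the joint analysis — before committing to the cost
of developing thousands of lines.

## The models

All models are fitted marker by marker to the phenotype vector *y* over all
subpopulations at once, and always contain the cross (subpopulation) main
effects *u_f*:

| id | model | marker effect | cofactors |
|----|-------|----------------|-----------|
| S1 | single marker, nested | *b_q(f)* per subpopulation | — |
| S2 | single marker, across | one *b_q* | — |
| J1 | joint composite mapping, nested | *b_q(f)* | *b_c(f)* |
| J2 | joint composite mapping, across | *b_q* | *b_c* |

e.g. J2 is `y = b0 + a_f u_f + x_q b_q + Σ_{c≠q} x_c b_c + e`.
Cofactors *c* are background markers chosen by L1-penalised regression
(10-fold cross-validated penalty) over 1.5 cM genome segments — method 1
screens one random marker per segment, method 2 re-screens every marker of
the segments that produced a method-1 cofactor. When marker *q* is tested,
cofactors within 5 cM of it are dropped. Each marker's p-value is the ANOVA
F-test of the full against the reduced (no-marker-term) model.

Because simulation knows the true QTLs, the significance threshold at an
empirical error rate α\* is the α\*-quantile of the non-QTL marker
p-values; power 1−β\* is the fraction of QTLs falling below it, and
D(%) = |T−E|/T·100 measures effect-estimation error for detected QTLs.

## Worked example

```python
from nampower import ScenarioConfig, run_pipeline

cfg = ScenarioConfig(
    design="BC-NAM", n_subpops=10, n_per_sub=50,   # 500 individuals
    n_markers=1000, n_qtl=25, h2=0.8,              # geometric effects, a=0.90
    models=("S2", "J2"), n_runs=5, seed=42,
)
result = run_pipeline(cfg)
print(result.power_table[result.power_table.alpha_star == 0.01])
```

prints (five runs, synthetic founders):

```
model_id  alpha_star    power       se  mean_nominal_alpha  mean_d_percent  n_runs
      J2        0.01 0.243986 0.036104            0.000743       20.526479       5
      S2        0.01 0.167507 0.035167            0.000010       38.358302       5
```

Read: at an empirical false-positive rate of 1 % among non-QTL markers, the
composite model J2 recovers ~24 % of the 25 simulated QTLs versus ~17 % for
the single-marker model S2, and estimates the detected QTL effects with a
smaller relative error (D ≈ 21 % vs 38 %). The `mean_nominal_alpha` column
is the average p-value threshold that realises α\* = 0.01.

The same pipeline is scriptable from the shell:

```sh
nampower run --config scenario.yaml --out-dir results/
nampower simulate-founders --out-dir founders/   # just the founder panel
```

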