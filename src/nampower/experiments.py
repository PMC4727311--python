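"""Canonical scaled-down power experiments.

A full-scale study (25 runs x 10,000 SNPs x 2,100-5,000 individuals
x 4 models) is not desk-scale, so the packaged experiment reproduces its
qualitative structure at a reduced size: synthetic two-panel founders,
BC-NAM with 10 subpopulations x 50 individuals, 1,000 markers on a genome
of 10 chromosomes x 100 cM (preserving roughly one QTL per 40 cM of map,
as at full scale), 25 QTLs on the geometric-effects series
with a = 0.90, and 10 simulation runs.

``scaled_power_experiment`` runs four scenario variants sharing founders
and per-run populations/architectures through label-derived child seeds
(paired comparisons):

* the purely additive trait at h^2 = 0.8 under all four models;
* the additive trait at h^2 = 0.5 (heritability trend, J2);
* QTL x background interactions (5 QTLs x 5 background markers) explaining
  5 / 15 / 25 % of genotypic variance (interaction trend, J2).
"""

from __future__ import annotations

from .config import ScenarioConfig
from .pipeline import run_pipeline

__all__ = ["scaled_power_experiment"]

INTERACTION_PROPS = (0.05, 0.15, 0.25)


def _power_from(table, model, alpha):
    row = table[(table.model_id == model) & (table.alpha_star == alpha)]
    return float(row["power"].iloc[0]), float(row["se"].iloc[0])


def scaled_power_experiment(seed: int = 1, n_runs: int = 10) -> dict:
    """Run the scaled power study; returns mean powers (and SEs) per cell.

    Keys: ``power_<model>_additive_a<level>`` for the four models at
    alpha* in {0.05, 0.01}; ``power_J2_h2_05_a<level>``;
    ``power_J2_int<prop>_a<level>``.
    """
    out: dict[str, float] = {}

    base = dict(n_runs=n_runs, seed=seed)
    main = run_pipeline(ScenarioConfig(models=("S1", "S2", "J1", "J2"), **base))
    for model in ("S1", "S2", "J1", "J2"):
        for alpha, tag in ((0.05, "a05"), (0.01, "a01")):
            p, se = _power_from(main.power_table, model, alpha)
            out[f"power_{model}_additive_{tag}"] = p
            out[f"se_{model}_additive_{tag}"] = se

    low_h2 = run_pipeline(ScenarioConfig(models=("J2",), h2=0.5, **base))
    for alpha, tag in ((0.05, "a05"), (0.01, "a01")):
        p, se = _power_from(low_h2.power_table, "J2", alpha)
        out[f"power_J2_h2_05_{tag}"] = p
        out[f"se_J2_h2_05_{tag}"] = se

    for prop in INTERACTION_PROPS:
        res = run_pipeline(
            ScenarioConfig(
                models=("J2",), n_qtl_int=5, n_bg=5, interaction_prop=prop, **base
            )
        )
        key = f"int{int(round(prop * 100)):02d}"
        for alpha, tag in ((0.05, "a05"), (0.01, "a01")):
            p, se = _power_from(res.power_table, "J2", alpha)
            out[f"power_J2_{key}_{tag}"] = p
            out[f"se_J2_{key}_{tag}"] = se
    return out
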