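"""End-to-end scenario runner: founders -> design -> trait -> mapping -> power.

Each run re-simulates the NAM progeny, the trait architecture and the
phenotypic noise from run-indexed child seeds of the master seed, so runs
are independent replicates while the founder panel stays fixed within a
scenario.  Results are deterministic given (config, seed).
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as nio
from ._rng import child_rng
from .config import ScenarioConfig
from .designs import assign_subpop_sizes, make_bc_nam, make_dh_nam, make_ril_nam
from .founders import FounderPanel, filter_snps, synth_founders
from .mapping import ModelSpec, select_cofactors_m1, select_cofactors_m2, scan
from .power import RunPower, aggregate_runs, scan_power
from .traits import genotypic_values, phenotypes, sample_architecture, build_interactions

__all__ = ["PipelineResult", "build_founders", "build_population", "run_pipeline"]

log = logging.getLogger("nampower")

_BUILDERS = {"DH-NAM": make_dh_nam, "BC-NAM": make_bc_nam, "RIL-NAM": make_ril_nam}
_DESIGN_PANEL = {"DH-NAM": "panel1", "BC-NAM": "panel2", "RIL-NAM": "panel1"}


@dataclass
class PipelineResult:
    config: ScenarioConfig
    panel: FounderPanel = field(repr=False)
    runs: list[RunPower] = field(repr=False)
    power_table: pd.DataFrame = field(repr=False)


def build_founders(config: ScenarioConfig) -> FounderPanel:
    """Load-and-filter founders from files, or draw the synthetic panel."""
    if config.founder_geno_file:
        panel = nio.read_founder_panel(
            config.founder_geno_file, config.founder_map_file, config.founder_panels_file
        )
        return filter_snps(panel)
    return synth_founders(
        n_panel1=config.n_subpops,
        n_panel2=config.n_subpops,
        n_markers=config.n_markers,
        divergence=config.divergence,
        rng=child_rng(config.seed, "founders"),
        chrom_lengths_cm=config.chrom_lengths_cm,
    )


def _design_founders(panel: FounderPanel, config: ScenarioConfig):
    rows = panel.panel_rows(_DESIGN_PANEL[config.design])
    if rows.size < config.n_subpops:
        raise ValueError(
            f"{config.design} needs {config.n_subpops} founders in "
            f"{_DESIGN_PANEL[config.design]}, panel has {rows.size}"
        )
    rows = rows[: config.n_subpops]
    geno = np.asarray(panel.genotypes)[rows]
    ids = [panel.ids[int(r)] for r in rows]
    return geno, ids


def build_population(panel: FounderPanel, config: ScenarioConfig, rng):
    """One NAM population under the configured design and (possibly
    unbalanced) subpopulation sizes."""
    geno, ids = _design_founders(panel, config)
    if config.size_sd > 0:
        sizes = assign_subpop_sizes(config.n_subpops, config.total_individuals, config.size_sd, rng)
    else:
        sizes = config.n_per_sub
    return _BUILDERS[config.design](
        geno, panel.common_genotype, ids, panel.gmap, n_per_sub=sizes, rng=rng
    )


def run_pipeline(config: ScenarioConfig, out_dir: str | None = None) -> PipelineResult:
    """Execute the full scenario and return the aggregated power table.

    When ``out_dir`` is given, the founder panel, per-run phenotypes,
    cofactors and scans, the power table, and a machine-readable JSON log
    are written beneath it.
    """
    t0 = time.time()
    out = Path(out_dir) if out_dir else None
    stage_log: list[dict] = []

    def note(stage: str, **info) -> None:
        entry = {"stage": stage, "elapsed_s": round(time.time() - t0, 2), **info}
        stage_log.append(entry)
        log.info("%s %s", stage, info)

    panel = build_founders(config)
    note("founders", n_founders=panel.n_founders, n_markers=panel.n_markers)
    if out:
        out.mkdir(parents=True, exist_ok=True)
        nio.write_founder_panel(out / "founders", panel)
        config.to_yaml(out / "config.yaml")

    design_geno, _ = _design_founders(panel, config)
    parental = np.vstack([design_geno, panel.common_genotype])

    runs: list[RunPower] = []
    needs_cofactors = any(m in ("J1", "J2") for m in config.models)
    for r in range(config.n_runs):
        run_dir = out / f"run_{r:02d}" if out else None
        if run_dir:
            run_dir.mkdir(exist_ok=True)
        try:
            pop = build_population(panel, config, child_rng(config.seed, "design", r))
            trng = child_rng(config.seed, "trait", r)
            arch = sample_architecture(pop.n_markers, config.n_qtl, config.a, trng)
            if config.interaction_prop > 0:
                arch = build_interactions(
                    arch, config.n_qtl_int, config.n_bg, config.interaction_prop, pop, trng
                )
            sigma_g2 = float(np.var(genotypic_values(parental, arch)))
            # dedicated noise stream: scenario variants (heritability,
            # interaction proportion) share the same noise normals, so
            # cross-scenario comparisons are paired (common random numbers)
            phen = phenotypes(
                genotypic_values(pop, arch), config.h2, sigma_g2,
                child_rng(config.seed, "noise", r),
            )
            y = phen.phenotypes
            note("trait", run=r, n_individuals=pop.n_individuals, sigma_g2=round(sigma_g2, 4))

            cofactors = None
            if needs_cofactors:
                crng = child_rng(config.seed, "cofactors", r)
                cofactors = select_cofactors_m1(pop, y, config.segment_cm, crng)
                if config.cofactor_method == "M2":
                    cofactors = select_cofactors_m2(cofactors, pop, y, config.segment_cm, crng)
                note("cofactors", run=r, method=config.cofactor_method, n=len(cofactors))

            if run_dir:
                ind_ids = [f"ind_{i}" for i in range(pop.n_individuals)]
                nio.write_phenotypes(run_dir / "phenotypes.tsv", ind_ids, phen.genotypic_values, y)
                if cofactors is not None:
                    pd.DataFrame(
                        {
                            "marker_id": pop.gmap.marker_ids[cofactors.indices],
                            "segment_id": cofactors.segments,
                            "method": cofactors.method,
                        }
                    ).to_csv(run_dir / "cofactors.tsv", sep="\t", index=False)

            for model_id in config.models:
                spec = ModelSpec(
                    model_id,
                    cofactor_method=config.cofactor_method if model_id in ("J1", "J2") else "none",
                    exclusion_window_cm=config.exclusion_window_cm,
                )
                res = scan(pop, y, spec, cofactors if spec.uses_cofactors else None)
                runs.append(scan_power(res, arch, config.alphas))
                if run_dir:
                    nio.write_scan(run_dir / f"scan_{model_id}.tsv", res)
                note("scan", run=r, model=model_id)
        except Exception:
            log.exception("pipeline aborted in run %d (partial outputs retained)", r)
            raise

    table = aggregate_runs(runs) if config.n_runs >= 2 else pd.DataFrame()
    note("power", n_runs=config.n_runs)
    if out:
        nio.write_power(out / "power.tsv", table, scenario_id=config.design)
        (out / "pipeline_log.json").write_text(json.dumps(stage_log, indent=1))
    return PipelineResult(config=config, panel=panel, runs=runs, power_table=table)
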