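"""Power of QTL detection at fixed empirical type-I-error rates.

Because the simulation knows which markers are QTLs, the significance
threshold for an empirical error rate alpha* is the alpha*-quantile (lower
order statistic) of the non-QTL marker p-values; a QTL whose p-value falls
strictly below the threshold counts as correctly identified.  Power
1 - beta* is the fraction of QTLs so identified.  For identified QTLs the
relative effect-estimation error D(%) = |T - E| / T * 100 compares the
simulated effect T with the model estimate E.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mapping import ScanResult, effect_table
from .traits import TraitArchitecture

__all__ = [
    "DEFAULT_ALPHAS",
    "empirical_thresholds",
    "power_at",
    "effect_difference",
    "scan_power",
    "aggregate_runs",
]

#: default empirical type-I-error grid (0.05 included as in the reported tables)
DEFAULT_ALPHAS = (0.5, 0.1, 0.05, 0.01, 0.001, 0.0001, 0.00001)


def empirical_thresholds(nonqtl_pvalues, alphas=DEFAULT_ALPHAS) -> dict[float, float]:
    """Lower empirical quantiles of the non-QTL p-value distribution.

    threshold(alpha) is the ceil(alpha*n)-th order statistic, so the
    fraction of non-QTL markers strictly below it is at most alpha.
    """
    p = np.sort(np.asarray(nonqtl_pvalues, float))
    p = p[np.isfinite(p)]
    if p.size == 0:
        raise ValueError("no non-QTL p-values supplied")
    out = {}
    for a in alphas:
        if not 0.0 < a < 1.0:
            raise ValueError("alpha levels must lie in (0, 1)")
        k = int(np.ceil(a * p.size))
        out[float(a)] = float(p[max(k - 1, 0)])
    return out


def power_at(qtl_pvalues, thresholds: dict[float, float]) -> dict[float, float]:
    """Power per alpha*: fraction of QTLs with p strictly below threshold.

    Ties with the threshold count as not detected (conservative).
    """
    p = np.asarray(qtl_pvalues, float)
    p = p[np.isfinite(p)]
    if p.size == 0:
        raise ValueError("no QTL p-values supplied")
    return {a: float((p < t).mean()) for a, t in thresholds.items()}


def effect_difference(T: float, E: float) -> float:
    """Relative effect-estimation error D(%) = |T - E| / T * 100."""
    if T <= 0:
        raise ValueError("true effect T must be positive")
    return abs(T - E) / T * 100.0


@dataclass
class RunPower:
    """One run's power summary for one model."""

    model_id: str
    thresholds: dict[float, float]
    power: dict[float, float]
    mean_d_percent: dict[float, float]  # over correctly identified QTLs
    n_qtl_tested: int
    n_nonqtl_tested: int


def scan_power(
    result: ScanResult,
    arch: TraitArchitecture,
    alphas=DEFAULT_ALPHAS,
) -> RunPower:
    """Thresholds, power and D(%) for one scan.

    Markers flagged untested (monomorphic / fully aliased) are excluded from
    both the non-QTL pool and the QTL denominator.
    """
    is_qtl = np.zeros(len(result.table), bool)
    is_qtl[arch.qtl_indices] = True
    tested = result.tested
    p = result.p_values
    thr = empirical_thresholds(p[tested & ~is_qtl], alphas)
    qtl_p = p[tested & is_qtl]
    pw = power_at(qtl_p, thr)
    eff = effect_table(result, arch)
    d_percent = {}
    for a, t in thr.items():
        hit = eff[eff["p_value"] < t]
        d_percent[a] = (
            float(np.mean([effect_difference(T, E) for T, E in zip(hit["true_effect"], hit["estimated_effect"])]))
            if len(hit)
            else float("nan")
        )
    return RunPower(
        model_id=result.model_id,
        thresholds=thr,
        power=pw,
        mean_d_percent=d_percent,
        n_qtl_tested=int((tested & is_qtl).sum()),
        n_nonqtl_tested=int((tested & ~is_qtl).sum()),
    )


def aggregate_runs(runs: list[RunPower]) -> pd.DataFrame:
    """Mean power with standard errors across simulation runs.

    One row per (model, alpha*): mean power, SE = sd/sqrt(runs), the mean
    nominal alpha (average of the per-run threshold p-values), and the mean
    D(%) over runs where at least one QTL was identified.
    """
    if len(runs) < 2:
        raise ValueError("need at least 2 runs to aggregate")
    grids = {tuple(sorted(r.power.keys())) for r in runs}
    if len(grids) != 1:
        raise ValueError("inconsistent alpha* grids across runs")
    models = sorted({r.model_id for r in runs})
    rows = []
    for model in models:
        sel = [r for r in runs if r.model_id == model]
        for a in sorted(next(iter(grids)), reverse=True):
            pw = np.array([r.power[a] for r in sel])
            thr = np.array([r.thresholds[a] for r in sel])
            d = np.array([r.mean_d_percent[a] for r in sel])
            d = d[np.isfinite(d)]
            rows.append(
                {
                    "model_id": model,
                    "alpha_star": a,
                    "power": pw.mean(),
                    "se": pw.std(ddof=1) / np.sqrt(len(pw)),
                    "mean_nominal_alpha": thr.mean(),
                    "mean_d_percent": d.mean() if d.size else float("nan"),
                    "n_runs": len(sel),
                }
            )
    return pd.DataFrame(rows)
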