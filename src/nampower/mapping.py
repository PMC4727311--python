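"""Joint QTL mapping across NAM subpopulations.

Four marker-by-marker linear models, all containing subpopulation (cross)
main effects:

* S1 — single marker model, marker effect nested within subpopulations
       (one substitution effect per subpopulation where the marker
       segregates);
* S2 — single marker model, one marker effect across subpopulations;
* J1 — joint composite interval mapping (JCIM), nested marker and cofactor
       effects;
* J2 — JCIM with across-subpopulation marker and cofactor effects.

Cofactors are background markers selected by L1-penalised regression over
1.5 cM genome segments: method 1 screens one random marker per segment,
method 2 re-screens every marker of the segments that held a method-1
cofactor.  When a marker is tested, cofactors within 5 cM of it on the same
chromosome are dropped from the model.  Each marker's p-value is the ANOVA
F-test of the full model against the model without the marker term(s).

The scan uses Frisch-Waugh residualisation grouped by identical
excluded-cofactor sets, which is algebraically exact: markers sharing a
base model (subpopulation effects + admitted cofactors) are tested against
a single orthonormal basis of that base.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats
from sklearn.linear_model import LassoCV
from sklearn.model_selection import KFold

from ._rng import as_rng
from .designs import NamPopulation
from .traits import TraitArchitecture

__all__ = [
    "ModelSpec",
    "CofactorSet",
    "ScanResult",
    "segment_genome",
    "select_cofactors_m1",
    "select_cofactors_m2",
    "scan",
    "effect_table",
]

MODEL_IDS = ("S1", "S2", "J1", "J2")


@dataclass
class ModelSpec:
    """Which model to fit and how cofactors are handled."""

    model_id: str
    cofactor_method: str = "none"  # none / M1 / M2
    exclusion_window_cm: float = 5.0

    def __post_init__(self) -> None:
        if self.model_id not in MODEL_IDS:
            raise ValueError(f"model_id must be one of {MODEL_IDS}")
        if self.model_id in ("S1", "S2") and self.cofactor_method != "none":
            raise ValueError("single marker models take no cofactors")

    @property
    def nested(self) -> bool:
        """Marker/cofactor effects nested within subpopulations?"""
        return self.model_id in ("S1", "J1")

    @property
    def uses_cofactors(self) -> bool:
        return self.model_id in ("J1", "J2")


@dataclass
class CofactorSet:
    """Markers admitted as cofactors, with their genome segments.

    ``weights`` are the absolute LASSO coefficients from selection; when the
    scan must shed cofactors to preserve residual degrees of freedom, the
    weakest are dropped first.
    """

    indices: np.ndarray
    method: str
    segments: np.ndarray  # segment id per cofactor
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, int)
        self.segments = np.asarray(self.segments, int)
        if self.weights is None:
            self.weights = np.ones(len(self.indices))
        self.weights = np.asarray(self.weights, float)

    def __len__(self) -> int:
        return len(self.indices)


@dataclass
class ScanResult:
    """Per-marker test results of one model on one trait."""

    table: pd.DataFrame = field(repr=False)
    model_id: str
    n_cofactors: int

    @property
    def p_values(self) -> np.ndarray:
        return self.table["p_value"].to_numpy()

    @property
    def tested(self) -> np.ndarray:
        return self.table["tested"].to_numpy()


def segment_genome(gmap, segment_cm: float = 1.5) -> np.ndarray:
    """Assign every marker to a half-open [k*L, (k+1)*L) cM bin within its
    chromosome; returns a globally unique integer segment id per marker."""
    if segment_cm <= 0:
        raise ValueError("segment length must be positive")
    seg = np.empty(gmap.n_markers, dtype=np.int64)
    offset = 0
    pos = gmap.pos_cm
    for sl in gmap.chrom_slices().values():
        p = pos[sl] - pos[sl].min()
        local = np.floor(p / segment_cm).astype(np.int64)
        seg[sl] = local + offset
        offset += local.max() + 1
    return seg


# ---------------------------------------------------------------------------
# cofactor selection
# ---------------------------------------------------------------------------

def _center_by_subpop(y: np.ndarray, subpop_index: np.ndarray) -> np.ndarray:
    out = np.asarray(y, float).copy()
    for s in np.unique(subpop_index):
        rows = subpop_index == s
        out[rows] -= out[rows].mean()
    return out


def _lasso_nonzero(X: np.ndarray, y: np.ndarray, seed: int) -> np.ndarray:
    """Indices of columns with non-zero LASSO coefficients at the 10-fold
    CV-error-minimising penalty (standardised predictors, seeded folds)."""
    if X.shape[0] < 10:
        raise ValueError("need at least 10 individuals for 10-fold cross-validation")
    sd = X.std(axis=0)
    Xs = (X - X.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    cv = KFold(n_splits=10, shuffle=True, random_state=seed)
    model = LassoCV(cv=cv, alphas=60, max_iter=5000, tol=1e-3)
    with warnings.catch_warnings():
        # fold-level coordinate-descent iteration caps are harmless here:
        # only the selected support matters, not exact fold coefficients
        from sklearn.exceptions import ConvergenceWarning

        warnings.simplefilter("ignore", ConvergenceWarning)
        model.fit(Xs, y)
    nz = np.flatnonzero(model.coef_ != 0)
    return nz, np.abs(model.coef_[nz])


def select_cofactors_m1(
    pop: NamPopulation,
    y: np.ndarray,
    segment_cm: float = 1.5,
    rng=None,
) -> CofactorSet:
    """Method 1: one random polymorphic marker per segment enters a joint
    LASSO of the (subpopulation-centred) phenotype; non-zero coefficients
    become cofactors."""
    rng = as_rng(rng)
    seg = segment_genome(pop.gmap, segment_cm)
    poly = pop.dosage.std(axis=0) > 0
    candidates = []
    for s in np.unique(seg):
        in_seg = np.flatnonzero((seg == s) & poly)
        if in_seg.size:
            candidates.append(int(rng.choice(in_seg)))
    if not candidates:
        return CofactorSet(np.empty(0, int), "M1", np.empty(0, int))
    candidates = np.array(candidates)
    yc = _center_by_subpop(y, pop.subpop_index)
    nz, w = _lasso_nonzero(pop.dosage[:, candidates].astype(float), yc, int(rng.integers(2**31)))
    kept = candidates[nz]
    return CofactorSet(kept, "M1", seg[kept], w)


def select_cofactors_m2(
    m1: CofactorSet,
    pop: NamPopulation,
    y: np.ndarray,
    segment_cm: float = 1.5,
    rng=None,
) -> CofactorSet:
    """Method 2: re-screen *all* polymorphic markers of the segments that
    produced a method-1 cofactor; non-zero LASSO coefficients are kept."""
    rng = as_rng(rng)
    if len(m1) == 0:
        return CofactorSet(np.empty(0, int), "M2", np.empty(0, int))
    seg = segment_genome(pop.gmap, segment_cm)
    poly = pop.dosage.std(axis=0) > 0
    candidates = np.flatnonzero(np.isin(seg, m1.segments) & poly)
    yc = _center_by_subpop(y, pop.subpop_index)
    nz, w = _lasso_nonzero(pop.dosage[:, candidates].astype(float), yc, int(rng.integers(2**31)))
    kept = candidates[nz]
    return CofactorSet(kept, "M2", seg[kept], w)


# ---------------------------------------------------------------------------
# the scan
# ---------------------------------------------------------------------------

def _nested_columns(dosage_col: np.ndarray, subpop_index: np.ndarray) -> np.ndarray:
    """Per-subpopulation marker columns, only for subpopulations where the
    marker segregates; empty (n, 0) if it segregates nowhere."""
    cols = []
    for s in np.unique(subpop_index):
        rows = subpop_index == s
        v = dosage_col[rows]
        if v.std() > 0:
            col = np.zeros_like(dosage_col, dtype=float)
            col[rows] = v
            cols.append(col)
    if not cols:
        return np.empty((dosage_col.shape[0], 0))
    return np.stack(cols, axis=1)


def _orth(A: np.ndarray, ref_scale: float | None = None) -> np.ndarray:
    """Orthonormal basis of the column space (rank via SVD tolerance).

    ``ref_scale`` anchors the rank tolerance to the scale of the columns
    *before* any residualisation, so a column numerically annihilated by
    projection (an aliased marker/cofactor) is treated as rank-deficient
    rather than kept as noise.
    """
    if A.shape[1] == 0:
        return np.empty((A.shape[0], 0))
    U, s, _ = np.linalg.svd(A, full_matrices=False)
    scale = max(s[0] if s.size else 0.0, ref_scale or 0.0)
    tol = scale * max(A.shape) * np.finfo(float).eps
    return U[:, s > tol]


def scan(
    pop: NamPopulation,
    y: np.ndarray,
    spec: ModelSpec,
    cofactors: CofactorSet | None = None,
) -> ScanResult:
    """Test every polymorphic marker under ``spec``.

    For each marker the full model (subpopulation effects + admitted
    cofactors + marker term) is compared against the reduced model (without
    the marker term) by an F-test on residual sums of squares; degrees of
    freedom follow the realised design ranks, so aliased columns are
    handled automatically.  Markers monomorphic in the whole population —
    or whose term is entirely aliased with the base model — are flagged
    untested (p = NaN).
    """
    y = np.asarray(y, float)
    n = pop.n_individuals
    if y.shape != (n,):
        raise ValueError("phenotype length must equal the population size")
    if spec.uses_cofactors and cofactors is None:
        raise ValueError(f"model {spec.model_id} requires a cofactor set")
    if not spec.uses_cofactors:
        cofactors = CofactorSet(np.empty(0, int), "none", np.empty(0, int))

    dosage = pop.dosage.astype(float)
    sub = pop.subpop_index
    Z = np.stack([(sub == s).astype(float) for s in np.unique(sub)], axis=1)
    poly = dosage.std(axis=0) > 0
    pos = pop.gmap.pos_cm
    chrom = pop.gmap.chromosome

    # pre-build each cofactor's column block once
    cof_blocks: dict[int, np.ndarray] = {}
    for c in cofactors.indices:
        col = dosage[:, c]
        cof_blocks[int(c)] = (
            _nested_columns(col, sub) if spec.nested else col[:, None]
        )

    # a cofactor with a genotype column identical to the tested marker IS that
    # marker (the c != q rule at genotype level): exclude it for that test
    dup_of_cof = {
        int(c): np.flatnonzero((dosage == dosage[:, [c]]).all(axis=0))
        for c in cofactors.indices
    }

    # markers grouped by the set of cofactors excluded for their test
    groups: dict[frozenset, list[int]] = {}
    w = spec.exclusion_window_cm
    for m in range(pop.n_markers):
        if not poly[m]:
            continue
        excluded = frozenset(
            int(c)
            for c in cofactors.indices
            if (chrom[c] == chrom[m] and abs(pos[c] - pos[m]) <= w)
            or c == m
            or m in dup_of_cof[int(c)]
        )
        groups.setdefault(excluded, []).append(m)

    p_values = np.full(pop.n_markers, np.nan)
    effects = np.full(pop.n_markers, np.nan)
    eff_by_sub: list = [None] * pop.n_markers
    tested = np.zeros(pop.n_markers, bool)
    n_cof_used = np.zeros(pop.n_markers, int)

    # degrees-of-freedom budget: the base model must leave room for the
    # widest marker term plus a minimum residual df; if the admitted
    # cofactors would overrun it, shed the weakest (smallest |LASSO
    # coefficient|) first — deterministic, order-independent
    min_resid_df = max(30, n // 10)
    marker_reserve = len(np.unique(sub)) if spec.nested else 1
    col_budget = n - Z.shape[1] - marker_reserve - min_resid_df
    weight_of = {int(c): float(w) for c, w in zip(cofactors.indices, cofactors.weights)}

    for excluded, markers in groups.items():
        admitted = [int(c) for c in cofactors.indices if int(c) not in excluded]
        admitted.sort(key=lambda c: (-weight_of[c], c))
        width = 0
        kept = []
        for c in admitted:
            w = cof_blocks[c].shape[1]
            if width + w > col_budget:
                continue
            width += w
            kept.append(c)
        admitted = sorted(kept)
        base = [Z] + [cof_blocks[c] for c in admitted]
        B = np.concatenate(base, axis=1)
        Q = _orth(B)
        rank_B = Q.shape[1]
        ry = y - Q @ (Q.T @ y)
        rss_reduced = float(ry @ ry)
        for m in markers:
            X = (
                _nested_columns(dosage[:, m], sub)
                if spec.nested
                else dosage[:, m][:, None]
            )
            rX = X - Q @ (Q.T @ X)
            col_norms = np.linalg.norm(X, axis=0)
            U = _orth(rX, ref_scale=float(col_norms.max(initial=0.0)))
            df_num = U.shape[1]
            df_den = n - rank_B - df_num
            if df_num == 0 or df_den <= 0:
                continue  # marker term aliased with the base model
            proj = U.T @ ry
            explained = float(proj @ proj)
            rss_full = max(rss_reduced - explained, 0.0)
            F = (explained / df_num) / (rss_full / df_den) if rss_full > 0 else np.inf
            p = float(stats.f.sf(F, df_num, df_den)) if np.isfinite(F) else 0.0
            b, *_ = np.linalg.lstsq(rX, ry, rcond=None)
            tested[m] = True
            p_values[m] = max(p, np.finfo(float).tiny)
            n_cof_used[m] = len(admitted)
            if spec.nested:
                eff_by_sub[m] = 2.0 * b  # homozygote-difference scale per subpop
                effects[m] = float(np.mean(np.abs(2.0 * b)))
            else:
                effects[m] = float(2.0 * b[0])

    if not tested.any():
        warnings.warn(
            f"model {spec.model_id}: no marker testable — the base model "
            f"(subpopulation effects + {len(cofactors)} cofactors) leaves no "
            "residual degrees of freedom at this sample size"
        )
    table = pd.DataFrame(
        {
            "marker_id": pop.gmap.marker_ids,
            "chromosome": chrom,
            "pos_cm": pos,
            "p_value": p_values,
            "effect": effects,
            "effects_by_subpop": eff_by_sub,
            "tested": tested,
            "n_cofactors_used": n_cof_used,
        }
    )
    return ScanResult(table=table, model_id=spec.model_id, n_cofactors=len(cofactors))


def effect_table(result: ScanResult, arch: TraitArchitecture) -> pd.DataFrame:
    """True vs estimated effect for every tested QTL, on the common
    homozygote-difference scale.

    The estimate is oriented to the simulated effect allele: across-model
    effects flip sign when the zero allele is the alternate one; nested
    estimates average the oriented per-subpopulation effects.
    """
    rows = []
    for q, T, allele in zip(arch.qtl_indices, arch.effects, arch.effect_allele):
        rec = result.table.iloc[int(q)]
        if not rec["tested"]:
            continue
        sign = 1.0 if allele == 1 else -1.0
        if rec["effects_by_subpop"] is not None:
            E = float(np.mean(sign * np.asarray(rec["effects_by_subpop"])))
        else:
            E = float(sign * rec["effect"])
        rows.append((int(q), rec["marker_id"], float(T), E, float(rec["p_value"])))
    return pd.DataFrame(rows, columns=["marker_index", "marker_id", "true_effect", "estimated_effect", "p_value"])
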