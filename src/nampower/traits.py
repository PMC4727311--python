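"""Quantitative-trait simulation: geometric-series QTL effects, additive
genotypic values, QTL x genetic-background interactions scaled to a target
variance fraction, and heritability-controlled phenotypic noise.

Effect sizes follow the geometric series 100(1-a)[1, a, a^2, ...]: with the
canonical pairings a = 0.90 for 25 QTLs, 0.96 for 50, 0.99 for 100, the
largest effect is 100(1-a) and the series sums to 100(1-a^l).  One of the
two alleles of each QTL (chosen at random) carries the full homozygous
effect q, the other zero; heterozygotes are worth q/2 (no dominance).
Phenotypes add N(0, (1-h^2) sigma_g^2 / h^2) noise, where sigma_g^2 is the
genetic variance among the parental inbreds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._rng import as_rng
from .designs import NamPopulation

__all__ = [
    "geometric_effects",
    "TraitArchitecture",
    "sample_architecture",
    "genotypic_values",
    "build_interactions",
    "PhenotypeSet",
    "phenotypes",
    "simulate_trait",
]

#: canonical (QTL count, geometric ratio) pairings
CANONICAL_L_A = {25: 0.90, 50: 0.96, 100: 0.99}


def geometric_effects(l: int, a: float) -> np.ndarray:
    """Effect magnitudes 100(1-a) * a^k, k = 0..l-1 (strictly decreasing)."""
    if l < 1:
        raise ValueError("l must be >= 1")
    if not 0.0 < a < 1.0:
        raise ValueError("geometric ratio a must lie in (0, 1)")
    return 100.0 * (1.0 - a) * a ** np.arange(l, dtype=float)


@dataclass
class TraitArchitecture:
    """QTL positions, effects, and (optional) background interactions."""

    qtl_indices: np.ndarray  # marker column indices, no duplicates
    effects: np.ndarray  # homozygous effect q per QTL (aligned with qtl_indices)
    effect_allele: np.ndarray  # 1 if the alternate allele carries q, else 0
    # interaction terms: parallel arrays + centering constants fixed at build time
    int_qtl: np.ndarray = field(default_factory=lambda: np.empty(0, int))
    int_bg: np.ndarray = field(default_factory=lambda: np.empty(0, int))
    int_coef: np.ndarray = field(default_factory=lambda: np.empty(0, float))
    int_center_qtl: np.ndarray = field(default_factory=lambda: np.empty(0, float))
    int_center_bg: np.ndarray = field(default_factory=lambda: np.empty(0, float))
    interaction_prop: float = 0.0

    def __post_init__(self) -> None:
        self.qtl_indices = np.asarray(self.qtl_indices, int)
        self.effects = np.asarray(self.effects, float)
        self.effect_allele = np.asarray(self.effect_allele, int)
        if len({len(self.qtl_indices), len(self.effects), len(self.effect_allele)}) != 1:
            raise ValueError("qtl_indices, effects and effect_allele must align")
        if np.unique(self.qtl_indices).size != self.qtl_indices.size:
            raise ValueError("QTL indices must be distinct")
        if (self.effects <= 0).any():
            raise ValueError("effects must be strictly positive")

    @property
    def n_qtl(self) -> int:
        return len(self.qtl_indices)


def sample_architecture(n_markers: int, l: int, a: float, rng=None) -> TraitArchitecture:
    """Sample ``l`` QTLs without replacement and assign the geometric effects
    in random order (a random permutation of the series)."""
    rng = as_rng(rng)
    if l > n_markers:
        raise ValueError("more QTLs requested than markers available")
    idx = rng.choice(n_markers, size=l, replace=False)
    eff = rng.permutation(geometric_effects(l, a))
    allele = rng.integers(2, size=l)
    return TraitArchitecture(qtl_indices=idx, effects=eff, effect_allele=allele)


def _additive(dosage: np.ndarray, arch: TraitArchitecture) -> np.ndarray:
    d = dosage[:, arch.qtl_indices].astype(float)
    d = np.where(arch.effect_allele == 1, d, 2.0 - d)
    return (d / 2.0) @ arch.effects


def _interaction(dosage: np.ndarray, arch: TraitArchitecture) -> np.ndarray:
    if arch.int_coef.size == 0:
        return np.zeros(dosage.shape[0])
    dq = dosage[:, arch.int_qtl].astype(float) - arch.int_center_qtl
    db = dosage[:, arch.int_bg].astype(float) - arch.int_center_bg
    return (dq * db) @ arch.int_coef


def genotypic_values(pop: NamPopulation | np.ndarray, arch: TraitArchitecture) -> np.ndarray:
    """Genotypic value = sum of QTL effects (dose-additive) plus any
    bilinear QTL x background interaction terms.

    Accepts a population or a raw dosage matrix (e.g. the founder panel, for
    computing sigma_g^2).
    """
    dosage = pop.dosage if isinstance(pop, NamPopulation) else np.asarray(pop)
    if arch.qtl_indices.max(initial=-1) >= dosage.shape[1]:
        raise IndexError("QTL index out of range for this marker set")
    return _additive(dosage, arch) + _interaction(dosage, arch)


def build_interactions(
    arch: TraitArchitecture,
    n_qtl_int: int,
    n_bg: int,
    target_prop: float,
    pop: NamPopulation,
    rng=None,
    max_redraws: int = 20,
) -> TraitArchitecture:
    """Attach QTL x background interactions explaining ``target_prop`` of the
    total genotypic variance in ``pop``.

    ``n_qtl_int`` QTLs are drawn from the architecture; each interacts with
    ``n_bg`` distinct non-QTL markers via a bilinear term on mean-centred
    dosages.  Raw N(0,1) coefficients are rescaled by the single constant c
    solving  Var(c*I) / Var(A + c*I) = target_prop  exactly (quadratic in c),
    so the realised proportion matches to numerical precision.  QTLs keep
    their additive effects.
    """
    if not 0.0 <= target_prop < 1.0:
        raise ValueError("target_prop must lie in [0, 1)")
    if n_qtl_int > arch.n_qtl:
        raise ValueError("n_qtl_int exceeds the number of QTLs")
    rng = as_rng(rng)
    if target_prop == 0.0 or n_qtl_int == 0 or n_bg == 0:
        return arch  # purely additive

    dosage = pop.dosage.astype(float)
    non_qtl = np.setdiff1d(np.arange(pop.n_markers), arch.qtl_indices)
    poly = np.flatnonzero(dosage[:, non_qtl].std(axis=0) > 0)
    non_qtl = non_qtl[poly]
    if non_qtl.size < n_bg:
        raise ValueError("not enough polymorphic non-QTL background markers")
    A = _additive(dosage, arch)
    v_A = A.var()

    for _ in range(max_redraws):
        chosen = rng.choice(arch.n_qtl, size=n_qtl_int, replace=False)
        iq = np.repeat(arch.qtl_indices[chosen], n_bg)
        ib = np.concatenate([rng.choice(non_qtl, size=n_bg, replace=False) for _ in range(n_qtl_int)])
        raw = rng.standard_normal(iq.size)
        cq = dosage[:, iq].mean(axis=0)
        cb = dosage[:, ib].mean(axis=0)
        I0 = ((dosage[:, iq] - cq) * (dosage[:, ib] - cb)) @ raw
        v_I = I0.var()
        if v_I > 0:
            break
        warnings.warn("degenerate interaction draw (zero variance); re-drawing")
    else:
        raise RuntimeError("could not draw a non-degenerate interaction set")

    cov = float(((A - A.mean()) * (I0 - I0.mean())).mean())  # ddof=0, matching var()
    p = target_prop
    c = (p * cov + np.sqrt(p * p * cov * cov + p * (1 - p) * v_I * v_A)) / ((1 - p) * v_I)
    return TraitArchitecture(
        qtl_indices=arch.qtl_indices,
        effects=arch.effects,
        effect_allele=arch.effect_allele,
        int_qtl=iq,
        int_bg=ib,
        int_coef=c * raw,
        int_center_qtl=cq,
        int_center_bg=cb,
        interaction_prop=target_prop,
    )


@dataclass
class PhenotypeSet:
    genotypic_values: np.ndarray
    phenotypes: np.ndarray
    h2: float
    sigma_g2: float  # genetic variance of the parental inbreds


def phenotypes(genotypic: np.ndarray, h2: float, sigma_g2_founders: float, rng=None) -> PhenotypeSet:
    """Add N(0, (1-h^2) sigma_g^2 / h^2) noise; h^2 = 1 gives zero noise."""
    if not 0.0 < h2 <= 1.0:
        raise ValueError("heritability must lie in (0, 1]")
    if sigma_g2_founders <= 0:
        raise ValueError("founder genetic variance must be positive")
    rng = as_rng(rng)
    g = np.asarray(genotypic, float)
    noise_var = (1.0 - h2) * sigma_g2_founders / h2
    noise = rng.normal(0.0, np.sqrt(noise_var), size=g.shape) if noise_var > 0 else 0.0
    return PhenotypeSet(genotypic_values=g, phenotypes=g + noise, h2=h2, sigma_g2=sigma_g2_founders)


def simulate_trait(
    pop: NamPopulation,
    founder_genotypes: np.ndarray,
    l: int,
    a: float,
    h2: float,
    rng=None,
    n_qtl_int: int = 0,
    n_bg: int = 0,
    interaction_prop: float = 0.0,
) -> tuple[TraitArchitecture, PhenotypeSet]:
    """Sample an architecture, optionally attach interactions, and emit
    phenotypes for ``pop``; sigma_g^2 is taken over the parental inbreds."""
    rng = as_rng(rng)
    arch = sample_architecture(pop.n_markers, l, a, rng)
    if interaction_prop > 0:
        arch = build_interactions(arch, n_qtl_int, n_bg, interaction_prop, pop, rng)
    sigma_g2 = float(np.var(genotypic_values(np.asarray(founder_genotypes), arch)))
    g = genotypic_values(pop, arch)
    return arch, phenotypes(g, h2, sigma_g2, rng)
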