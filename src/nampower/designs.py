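"""Meiosis and NAM mating designs.

The recombination model is Haldane's: crossover counts per chromosome are
Poisson with mean length/100 (Morgans), positions uniform in cM, no
interference.  At marker resolution this is equivalent to independent
Bernoulli "switch" events between adjacent markers with probability
``r = (1 - exp(-2 d / 100)) / 2`` for an interval of ``d`` cM, which is the
form used to simulate whole populations of gametes at once.

Three nested association mapping designs are provided, all crossing a set of
founder inbreds to one common parent:

* DH-NAM  — one doubled-haploid line per F1 gamete (fully homozygous);
* BC-NAM  — BC1 (one backcross to the common parent) advanced two selfing
  generations by single seed descent (BC1S2);
* RIL-NAM — F1 selfed for four generations by single seed descent (F5).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._rng import as_rng
from .genome import GeneticMap

__all__ = [
    "DiploidGenome",
    "NamPopulation",
    "simulate_gamete",
    "gametes",
    "self_ssd",
    "make_dh_nam",
    "make_bc_nam",
    "make_ril_nam",
    "assign_subpop_sizes",
]


@dataclass
class DiploidGenome:
    """Two haplotypes over a genetic map (alleles coded 0/1)."""

    haplotypes: np.ndarray  # shape (2, n_markers)
    gmap: GeneticMap

    def __post_init__(self) -> None:
        h = np.asarray(self.haplotypes)
        if h.shape != (2, self.gmap.n_markers):
            raise ValueError("haplotypes must have shape (2, n_markers)")
        self.haplotypes = h

    @property
    def dosage(self) -> np.ndarray:
        return self.haplotypes.sum(axis=0)


@dataclass
class NamPopulation:
    """NAM progeny: allele-dosage matrix plus subpopulation structure.

    ``dosage`` counts copies of the alternate allele (0/1/2); ``subpop_index``
    maps each individual to its subpopulation; ``subpop_founder`` names the
    non-common founder of each subpopulation.
    """

    dosage: np.ndarray  # (n_individuals, n_markers) int8
    subpop_index: np.ndarray  # (n_individuals,) int
    subpop_founder: list[str]
    design_tag: str
    gmap: GeneticMap
    haplotypes: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        self.subpop_index = np.asarray(self.subpop_index, dtype=np.int64)
        if self.dosage.shape[0] != self.subpop_index.shape[0]:
            raise ValueError("dosage rows and subpop_index length differ")
        if self.dosage.shape[1] != self.gmap.n_markers:
            raise ValueError("dosage columns and map size differ")

    @property
    def n_individuals(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosage.shape[1]

    @property
    def n_subpops(self) -> int:
        return len(self.subpop_founder)

    def subset(self, rows: np.ndarray) -> "NamPopulation":
        """Pure row selection (subset / unbalanced scenarios)."""
        rows = np.asarray(rows)
        sub_idx = self.subpop_index[rows]
        keep_subs = np.unique(sub_idx)
        remap = {int(s): i for i, s in enumerate(keep_subs)}
        return NamPopulation(
            dosage=self.dosage[rows],
            subpop_index=np.array([remap[int(s)] for s in sub_idx]),
            subpop_founder=[self.subpop_founder[int(s)] for s in keep_subs],
            design_tag=self.design_tag,
            gmap=self.gmap,
            haplotypes=None if self.haplotypes is None else self.haplotypes[rows],
        )


# ---------------------------------------------------------------------------
# meiosis
# ---------------------------------------------------------------------------

def simulate_gamete(parent: DiploidGenome, gmap: GeneticMap | None = None, rng=None) -> np.ndarray:
    """One gamete from ``parent`` by the literal crossover construction.

    Per chromosome: crossover count ~ Poisson(length/100), positions uniform
    in cM, starting haplotype by fair coin; alleles copied segment-wise.
    """
    rng = as_rng(rng)
    gmap = gmap or parent.gmap
    h = parent.haplotypes
    out = np.empty(gmap.n_markers, dtype=h.dtype)
    pos = gmap.pos_cm
    for sl in gmap.chrom_slices().values():
        p = pos[sl]
        length = p[-1] - p[0]
        n_x = rng.poisson(length / 100.0)
        xpos = np.sort(rng.uniform(p[0], p[0] + length, size=n_x)) if n_x else np.empty(0)
        start = rng.integers(2)
        # haplotype index at each marker = (start + #crossovers before it) mod 2
        chooser = (start + np.searchsorted(xpos, p, side="right")) % 2
        out[sl] = np.where(chooser == 0, h[0, sl], h[1, sl])
    return out


def _switch_probs(gmap: GeneticMap) -> np.ndarray:
    """Per-marker haplotype-switch probability under Haldane.

    First marker of each chromosome gets 0.5 (fresh coin); within a
    chromosome, r = (1 - exp(-2 d/100))/2 for the preceding interval.
    """
    pos = gmap.pos_cm
    r = np.empty(gmap.n_markers)
    for sl in gmap.chrom_slices().values():
        d = np.diff(pos[sl])
        r[sl.start] = 0.5
        r[sl.start + 1 : sl.stop] = 0.5 * (1.0 - np.exp(-2.0 * d / 100.0))
    return r


def gametes(haps: np.ndarray, gmap: GeneticMap, rng) -> np.ndarray:
    """Vectorised meiosis: one gamete from each of n diploids.

    ``haps`` has shape (n, 2, m); returns (n, m).  Statistically identical to
    ``simulate_gamete`` applied row-wise (no-interference equivalence).
    """
    rng = as_rng(rng)
    n, two, m = haps.shape
    if two != 2 or m != gmap.n_markers:
        raise ValueError("haps must have shape (n, 2, n_markers)")
    switches = rng.random((n, m)) < _switch_probs(gmap)
    chooser = np.empty((n, m), dtype=np.int64)
    for sl in gmap.chrom_slices().values():
        chooser[:, sl] = np.cumsum(switches[:, sl], axis=1) % 2
    return np.where(chooser == 0, haps[:, 0, :], haps[:, 1, :])


def self_ssd(haps: np.ndarray, gmap: GeneticMap, generations: int, rng) -> np.ndarray:
    """Advance each line by single seed descent: one selfed offspring per
    lineage per generation (two independent gametes of the same plant)."""
    rng = as_rng(rng)
    for _ in range(generations):
        haps = np.stack([gametes(haps, gmap, rng), gametes(haps, gmap, rng)], axis=1)
    return haps


# ---------------------------------------------------------------------------
# design builders
# ---------------------------------------------------------------------------

def _per_sub_sizes(n_per_sub, n_founders: int) -> np.ndarray:
    sizes = np.broadcast_to(np.asarray(n_per_sub, int), (n_founders,)).copy()
    if (sizes < 1).any():
        raise ValueError("every subpopulation needs at least one individual")
    return sizes


def _founder_haps(genotypes: np.ndarray) -> np.ndarray:
    g = np.asarray(genotypes)
    if not np.isin(g, (0, 2)).all():
        raise ValueError("founders must be homozygous (dosage 0 or 2 at every marker)")
    hap = (g // 2).astype(np.int8)
    return hap


def _f1_haps(founder_hap: np.ndarray, common_hap: np.ndarray, n: int) -> np.ndarray:
    """n copies of the (identical) F1 of founder x common parent."""
    return np.broadcast_to(
        np.stack([founder_hap, common_hap]), (n, 2, founder_hap.shape[0])
    ).copy()


def _assemble(
    per_sub_haps: list[np.ndarray],
    founder_ids: list[str],
    design_tag: str,
    gmap: GeneticMap,
    keep_haplotypes: bool,
) -> NamPopulation:
    haps = np.concatenate(per_sub_haps, axis=0)
    sizes = [h.shape[0] for h in per_sub_haps]
    subpop_index = np.repeat(np.arange(len(sizes)), sizes)
    return NamPopulation(
        dosage=haps.sum(axis=1).astype(np.int8),
        subpop_index=subpop_index,
        subpop_founder=list(founder_ids),
        design_tag=design_tag,
        gmap=gmap,
        haplotypes=haps if keep_haplotypes else None,
    )


def make_dh_nam(
    founder_genotypes: np.ndarray,
    common_genotype: np.ndarray,
    founder_ids: list[str],
    gmap: GeneticMap,
    n_per_sub: int = 100,
    rng=None,
    keep_haplotypes: bool = False,
) -> NamPopulation:
    """DH-NAM: per founder, ``n_per_sub`` doubled haploids of the F1."""
    rng = as_rng(rng)
    common_hap = _founder_haps(common_genotype[None, :])[0]
    sizes = _per_sub_sizes(n_per_sub, len(founder_ids))
    subs = []
    for hap, k in zip(_founder_haps(founder_genotypes), sizes):
        f1 = _f1_haps(hap, common_hap, int(k))
        g = gametes(f1, gmap, rng)
        subs.append(np.stack([g, g], axis=1))  # doubled gamete
    return _assemble(subs, founder_ids, "DH-NAM", gmap, keep_haplotypes)


def make_bc_nam(
    founder_genotypes: np.ndarray,
    common_genotype: np.ndarray,
    founder_ids: list[str],
    gmap: GeneticMap,
    n_per_sub: int = 100,
    rng=None,
    keep_haplotypes: bool = False,
) -> NamPopulation:
    """BC-NAM: BC1 to the common parent, then two SSD selfing generations
    (BC1S2).  Each BC1 individual carries one independent F1 gamete and one
    common-parent haplotype."""
    rng = as_rng(rng)
    common_hap = _founder_haps(common_genotype[None, :])[0]
    sizes = _per_sub_sizes(n_per_sub, len(founder_ids))
    subs = []
    for hap, k in zip(_founder_haps(founder_genotypes), sizes):
        f1 = _f1_haps(hap, common_hap, int(k))
        bc1 = np.stack(
            [gametes(f1, gmap, rng), np.broadcast_to(common_hap, (int(k), len(common_hap))).copy()],
            axis=1,
        )
        subs.append(self_ssd(bc1, gmap, 2, rng))
    return _assemble(subs, founder_ids, "BC-NAM", gmap, keep_haplotypes)


def make_ril_nam(
    founder_genotypes: np.ndarray,
    common_genotype: np.ndarray,
    founder_ids: list[str],
    gmap: GeneticMap,
    n_per_sub: int = 100,
    selfing_generations: int = 4,
    rng=None,
    keep_haplotypes: bool = False,
) -> NamPopulation:
    """RIL-NAM: F1 selfed ``selfing_generations`` times by SSD (F5 default)."""
    rng = as_rng(rng)
    common_hap = _founder_haps(common_genotype[None, :])[0]
    sizes = _per_sub_sizes(n_per_sub, len(founder_ids))
    subs = []
    for hap, k in zip(_founder_haps(founder_genotypes), sizes):
        f1 = _f1_haps(hap, common_hap, int(k))
        subs.append(self_ssd(f1, gmap, selfing_generations, rng))
    return _assemble(subs, founder_ids, "RIL-NAM", gmap, keep_haplotypes)


def assign_subpop_sizes(n_sub: int, total: int, sd: float, rng=None) -> np.ndarray:
    """Subpopulation sizes ~ Normal(total/n_sub, sd), rounded, clipped to
    >= 1, then nudged by +-1 on random subpopulations until they sum to
    ``total`` exactly.  sd=0 with divisible total gives equal sizes."""
    if total < n_sub:
        raise ValueError("total must be >= n_sub (every subpopulation needs >= 1)")
    if sd < 0:
        raise ValueError("sd must be >= 0")
    rng = as_rng(rng)
    sizes = np.clip(np.round(rng.normal(total / n_sub, sd, size=n_sub)).astype(int), 1, None)
    while sizes.sum() != total:
        i = int(rng.integers(n_sub))
        if sizes.sum() < total:
            sizes[i] += 1
        elif sizes[i] > 1:
            sizes[i] -= 1
    return sizes
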