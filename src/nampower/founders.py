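"""Founder panels: filtering, panel expansion, random mating, DH derivation,
and a fully synthetic two-panel generator.

The empirical route starts from a small set of homozygous-inbred SNPs,
filters on minor allele frequency and missingness, expands the panel to a
genome-wide marker set, erodes the original LD by long-term random mating,
and re-derives a set of homozygous "simulated parental inbreds" as doubled
haploids.  The synthetic route draws a two-panel (adapted vs exotic) founder
set directly from divergence-controlled allele frequencies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rng import as_rng
from .designs import gametes
from .genome import GeneticMap

__all__ = [
    "FounderPanel",
    "RandomMatingPopulation",
    "filter_snps",
    "expand_snp_panel",
    "random_mating",
    "derive_dh_lines",
    "synth_founders",
]


class EmptyPanelError(ValueError):
    """Raised when SNP filtering removes every marker."""


@dataclass
class FounderPanel:
    """Homozygous inbred founders over a genetic map.

    ``genotypes`` is inbreds x markers allele dosage; values are 0 or 2
    (founders are homozygous), with NaN allowed for missing calls on the
    empirical import path.  ``panel_label`` assigns each inbred to
    ``panel1`` (adapted), ``panel2`` (exotic) or ``common``.
    """

    genotypes: np.ndarray = field(repr=False)
    ids: list[str]
    panel_label: np.ndarray
    common_parent_id: str
    gmap: GeneticMap

    def __post_init__(self) -> None:
        g = np.asarray(self.genotypes, dtype=float)
        bad = ~(np.isnan(g) | (g == 0) | (g == 2))
        if bad.any():
            j = int(np.argwhere(bad)[0, 1])
            raise ValueError(
                f"marker {self.gmap.marker_ids[j]!r}: founder dosages must be 0, 2 or missing "
                "(biallelic, homozygous)"
            )
        if g.shape != (len(self.ids), self.gmap.n_markers):
            raise ValueError("genotype matrix shape does not match ids x map")
        self.panel_label = np.asarray(self.panel_label, dtype=object)
        if list(self.panel_label).count("common") != 1:
            raise ValueError("exactly one common parent required")
        if self.ids[int(np.argwhere(self.panel_label == "common")[0, 0])] != self.common_parent_id:
            raise ValueError("common_parent_id does not match the 'common' labelled inbred")
        self.genotypes = g if np.isnan(g).any() else g.astype(np.int8)

    @property
    def n_founders(self) -> int:
        return len(self.ids)

    @property
    def n_markers(self) -> int:
        return self.gmap.n_markers

    def allele_freq(self) -> np.ndarray:
        """Alternate-allele frequency per marker over non-missing calls."""
        g = np.asarray(self.genotypes, float)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(g, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        p = self.allele_freq()
        return np.minimum(p, 1.0 - p)

    def missing_fraction(self) -> np.ndarray:
        return np.isnan(np.asarray(self.genotypes, float)).mean(axis=0)

    def panel_rows(self, label: str) -> np.ndarray:
        return np.flatnonzero(self.panel_label == label)

    @property
    def common_genotype(self) -> np.ndarray:
        return np.asarray(self.genotypes)[self.panel_rows("common")[0]]

    def subset_markers(self, idx) -> "FounderPanel":
        idx = np.asarray(idx)
        return FounderPanel(
            genotypes=np.asarray(self.genotypes)[:, idx],
            ids=self.ids,
            panel_label=self.panel_label,
            common_parent_id=self.common_parent_id,
            gmap=self.gmap.subset(idx),
        )


def filter_snps(panel: FounderPanel, maf_min: float = 0.05, missing_max: float = 0.20) -> FounderPanel:
    """Retain markers with MAF >= ``maf_min`` (over non-missing calls) and
    missing fraction <= ``missing_max``; column order preserved.

    Raises ``EmptyPanelError`` if nothing survives.  Idempotent.
    """
    if not (0 <= maf_min <= 1 and 0 <= missing_max <= 1):
        raise ValueError("maf_min and missing_max must lie in [0, 1]")
    keep = (panel.maf() >= maf_min) & (panel.missing_fraction() <= missing_max)
    if not keep.any():
        raise EmptyPanelError("all markers removed by the MAF/missingness filter")
    return panel.subset_markers(np.flatnonzero(keep))


def expand_snp_panel(
    panel: FounderPanel,
    n_target: int,
    chrom_lengths_cm: dict[str, float],
    rng=None,
) -> FounderPanel:
    """Expand to ``n_target`` evenly spaced markers, per-chromosome counts
    proportional to chromosome length (largest-remainder rounding).

    Each new marker copies the founder alleles of one original SNP sampled
    uniformly with replacement, preserving the allele-frequency spectrum and
    population structure of the source panel.
    """
    if panel.n_markers == 0:
        raise EmptyPanelError("cannot expand an empty panel")
    rng = as_rng(rng)
    new_map = GeneticMap.uniform(chrom_lengths_cm, n_target)
    src = rng.integers(panel.n_markers, size=new_map.n_markers)
    return FounderPanel(
        genotypes=np.asarray(panel.genotypes)[:, src],
        ids=panel.ids,
        panel_label=panel.panel_label,
        common_parent_id=panel.common_parent_id,
        gmap=new_map,
    )


@dataclass
class RandomMatingPopulation:
    """Phased diploid population under random union of gametes."""

    haplotypes: np.ndarray = field(repr=False)  # (n, 2, m)
    gmap: GeneticMap
    generation: int = 0

    @property
    def size(self) -> int:
        return self.haplotypes.shape[0]

    def allele_freq(self) -> np.ndarray:
        return self.haplotypes.mean(axis=(0, 1))


def random_mating(
    source: FounderPanel | RandomMatingPopulation,
    generations: int,
    pop_size: int,
    rng=None,
) -> RandomMatingPopulation:
    """Random union of gametes (monoecious, selfing allowed) at constant size.

    From a ``FounderPanel`` the first generation draws both parents of each
    of ``pop_size`` offspring uniformly from the founders; subsequent
    generations draw parents uniformly from the previous generation.
    Expected allele frequencies are conserved (drift only).
    """
    if pop_size < 2:
        raise ValueError("pop_size must be >= 2")
    if generations < 1:
        raise ValueError("generations must be >= 1")
    rng = as_rng(rng)
    if isinstance(source, FounderPanel):
        g = np.asarray(source.genotypes)
        if np.isnan(np.asarray(g, float)).any():
            raise ValueError("founder panel contains missing calls; filter/complete first")
        hap = (g // 2).astype(np.int8)
        haps = np.stack([hap, hap], axis=1)  # founders are homozygous
        gmap = source.gmap
        gen0 = 0
    else:
        haps, gmap, gen0 = source.haplotypes, source.gmap, source.generation
    for _ in range(generations):
        mothers = rng.integers(haps.shape[0], size=pop_size)
        fathers = rng.integers(haps.shape[0], size=pop_size)
        haps = np.stack(
            [gametes(haps[mothers], gmap, rng), gametes(haps[fathers], gmap, rng)], axis=1
        )
    return RandomMatingPopulation(haplotypes=haps, gmap=gmap, generation=gen0 + generations)


def derive_dh_lines(pop: RandomMatingPopulation, n: int, rng=None) -> np.ndarray:
    """Doubled-haploid genotypes from ``n`` distinct individuals: one gamete
    each, doubled — every output line is fully homozygous (dosage 0/2)."""
    if n > pop.size:
        raise ValueError("cannot sample more DH lines than individuals")
    rng = as_rng(rng)
    rows = rng.choice(pop.size, size=n, replace=False)
    g = gametes(pop.haplotypes[rows], pop.gmap, rng)
    return (2 * g).astype(np.int8)


def synth_founders(
    n_panel1: int = 21,
    n_panel2: int = 29,
    n_markers: int = 2000,
    divergence: float = 0.4,
    rng=None,
    chrom_lengths_cm: dict[str, float] | None = None,
    maf_min: float = 0.05,
) -> FounderPanel:
    """Synthetic two-panel founder set with one common parent.

    Per marker an ancestral frequency is drawn, then the two panels are
    pushed apart by a ``divergence``-controlled shift, emulating an adapted
    (panel 1) vs exotic (panel 2) germplasm split that separates on the
    first principal coordinate.  The common parent is drawn from panel-1
    frequencies (an elite adapted line).  Markers failing the MAF filter
    across all founders are re-drawn so the returned panel satisfies
    MAF >= ``maf_min`` at every marker.
    """
    if min(n_panel1, n_panel2, n_markers) < 1:
        raise ValueError("counts must be >= 1")
    if not 0 <= divergence <= 1:
        raise ValueError("divergence must lie in [0, 1]")
    rng = as_rng(rng)
    if chrom_lengths_cm is None:
        chrom_lengths_cm = {f"C{i + 1}": 100.0 for i in range(10)}
    gmap = GeneticMap.uniform(chrom_lengths_cm, n_markers)
    n_total = n_panel1 + n_panel2 + 1

    def draw(m: int) -> tuple[np.ndarray, ...]:
        p0 = rng.uniform(0.15, 0.85, size=m)
        sign = rng.choice((-1.0, 1.0), size=m)
        shift = divergence * np.minimum(p0, 1 - p0)
        p1 = np.clip(p0 - sign * shift, 0.02, 0.98)
        p2 = np.clip(p0 + sign * shift, 0.02, 0.98)
        g1 = 2 * (rng.random((n_panel1, m)) < p1)
        g2 = 2 * (rng.random((n_panel2, m)) < p2)
        gc = 2 * (rng.random((1, m)) < p1)
        return np.concatenate([g1, gc, g2], axis=0).astype(np.int8)

    geno = draw(n_markers)
    for _ in range(100):
        p = geno.mean(axis=0) / 2.0
        bad = np.flatnonzero(np.minimum(p, 1 - p) < maf_min)
        if bad.size == 0:
            break
        geno[:, bad] = draw(bad.size)
    else:
        warnings.warn("some markers remained below the MAF floor after re-draws")

    ids = (
        [f"P1_{i + 1:03d}" for i in range(n_panel1)]
        + ["COMMON"]
        + [f"P2_{i + 1:03d}" for i in range(n_panel2)]
    )
    labels = np.array(["panel1"] * n_panel1 + ["common"] + ["panel2"] * n_panel2, dtype=object)
    return FounderPanel(
        genotypes=geno,
        ids=ids,
        panel_label=labels,
        common_parent_id="COMMON",
        gmap=gmap,
    )
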