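"""Founder filtering, panel expansion, random mating and DH derivation."""

import numpy as np
import pandas as pd
import pytest

from nampower import GeneticMap, FounderPanel, filter_snps, expand_snp_panel
from nampower.founders import (
    EmptyPanelError,
    RandomMatingPopulation,
    derive_dh_lines,
    random_mating,
    synth_founders,
)
from nampower.popgen import mrd, pcoa, ld_pairs


def _panel(geno, labels=None, chrom="1"):
    geno = np.asarray(geno, float)
    n, m = geno.shape
    gmap = GeneticMap(
        pd.DataFrame(
            {
                "marker_id": [f"m{j}" for j in range(m)],
                "chromosome": chrom,
                "pos_bp": (np.arange(m) + 1) * 674_000,
            }
        )
    )
    if labels is None:
        labels = np.array(["panel1"] * (n - 1) + ["common"], object)
    ids = [f"L{i}" for i in range(n - 1)] + ["CP"]
    return FounderPanel(geno, ids, labels, "CP", gmap)


class TestFilterSnps:
    def test_matches_bruteforce_column_check(self):
        rng = np.random.default_rng(42)
        geno = rng.choice([0.0, 2.0], size=(8, 10))
        geno[rng.random((8, 10)) < 0.2] = np.nan
        panel = _panel(geno)
        kept = filter_snps(panel, maf_min=0.05, missing_max=0.20)
        expect = []
        for j in range(10):
            col = geno[:, j]
            obs = col[~np.isnan(col)]
            p = obs.mean() / 2
            if min(p, 1 - p) >= 0.05 and np.isnan(col).mean() <= 0.20:
                expect.append(f"m{j}")
        assert list(kept.gmap.marker_ids) == expect

    def test_monomorphic_matrix_raises_empty(self):
        panel = _panel(np.full((6, 5), 2.0))
        with pytest.raises(EmptyPanelError):
            filter_snps(panel)

    def test_idempotent(self, small_panel):
        once = filter_snps(small_panel)
        twice = filter_snps(once)
        assert np.array_equal(np.asarray(once.genotypes), np.asarray(twice.genotypes))

    def test_non_biallelic_value_rejected_with_marker_id(self):
        geno = np.array([[0.0, 1.0], [2.0, 0.0]])
        with pytest.raises(ValueError, match="m1"):
            _panel(geno)


class TestExpandPanel:
    def test_counts_and_spectrum(self, small_panel):
        out = expand_snp_panel(small_panel, 500, {"1": 10.0, "2": 30.0}, rng=1)
        assert out.n_markers == 500
        counts = pd.Series(out.gmap.chromosome).value_counts()
        assert counts["1"] == 125 and counts["2"] == 375
        # every new column is a copy of some original column
        src = {tuple(col) for col in np.asarray(small_panel.genotypes).T}
        assert all(tuple(col) in src for col in np.asarray(out.genotypes).T)

    def test_empty_source_errors(self, small_panel):
        empty = small_panel.subset_markers(np.empty(0, int))
        with pytest.raises(EmptyPanelError):
            expand_snp_panel(empty, 10, {"1": 10.0})


class TestRandomMating:
    def test_opposite_homozygotes_give_heterozygous_offspring(self):
        panel = _panel(np.array([[0.0, 0.0, 0.0], [2.0, 2.0, 2.0]]),
                       labels=np.array(["panel1", "common"], object))
        pop = random_mating(panel, generations=1, pop_size=50, rng=3)
        dosage = pop.haplotypes.sum(axis=1)
        # each offspring draws parents uniformly; when parents differ it is het
        assert set(np.unique(dosage)) <= {0, 1, 2}
        assert (dosage == 1).mean() == pytest.approx(0.5, abs=0.2)

    def test_conserves_allele_frequency_in_expectation(self, small_panel):
        p0 = small_panel.allele_freq()
        freqs = []
        for rep in range(30):
            pop = random_mating(small_panel, generations=5, pop_size=200, rng=1000 + rep)
            freqs.append(pop.allele_freq())
        mean_shift = np.abs(np.mean(freqs, axis=0) - p0).mean()
        # binomial SE of the replicate mean is ~ sqrt(p q / (2N*reps)) ~ 0.003
        assert mean_shift < 0.015

    def test_ld_erodes_with_generations(self):
        # start from two complementary haplotype blocks: maximal LD
        geno = np.array([[0.0] * 12, [2.0] * 12] * 4)
        panel = _panel(geno, labels=np.array(["panel1"] * 7 + ["common"], object))
        r2 = []
        for gens in (1, 12):
            pop = random_mating(panel, generations=gens, pop_size=400, rng=5)
            pairs = ld_pairs(pop.haplotypes.sum(axis=1), pop.gmap, rng=0)
            far = pairs[pairs.distance > 5]
            r2.append(far.r2.mean())
        assert r2[1] < r2[0]

    def test_pop_size_below_two_errors(self, small_panel):
        with pytest.raises(ValueError):
            random_mating(small_panel, generations=1, pop_size=1)


class TestDeriveDh:
    def test_dh_lines_fully_homozygous_and_balanced(self, small_panel):
        pop = random_mating(small_panel, generations=2, pop_size=100, rng=9)
        dh = derive_dh_lines(pop, 51, rng=10)
        assert dh.shape == (51, small_panel.n_markers)
        assert set(np.unique(dh)) <= {0, 2}

    def test_heterozygous_parent_splits_evenly(self):
        gmap = GeneticMap.uniform({"1": 1.0}, 1)
        haps = np.zeros((10_000, 2, 1), dtype=np.int8)
        haps[:, 1, 0] = 1  # every individual heterozygous at the single marker
        pop = RandomMatingPopulation(haps, gmap)
        dh = derive_dh_lines(pop, 10_000, rng=11)
        frac = (dh[:, 0] == 2).mean()
        assert abs(frac - 0.5) < 3 * 0.5 / np.sqrt(10_000)


class TestSynthFounders:
    def test_outputs_homozygous_and_maf_filtered(self, small_panel):
        g = np.asarray(small_panel.genotypes)
        assert set(np.unique(g)) <= {0, 2}
        assert small_panel.maf().min() >= 0.05
        assert list(small_panel.panel_label).count("common") == 1

    def test_divergent_panels_separate_on_first_axis(self):
        panel = synth_founders(30, 29, 2000, divergence=0.4, rng=202)
        d = mrd(np.asarray(panel.genotypes), panel.ids)
        coords, _ = pcoa(d, 2)
        axis1 = coords["PCo1"].to_numpy()
        is_p2 = panel.panel_label == "panel2"
        observed = abs(axis1[is_p2].mean() - axis1[~is_p2].mean())
        rng = np.random.default_rng(0)
        perm = []
        for _ in range(500):
            lab = rng.permutation(is_p2)
            perm.append(abs(axis1[lab].mean() - axis1[~lab].mean()))
        p = (np.sum(np.asarray(perm) >= observed) + 1) / 501
        assert p < 0.01

    def test_zero_divergence_shows_no_separation(self):
        panel = synth_founders(8, 8, 150, divergence=0.0, rng=77)
        d = mrd(np.asarray(panel.genotypes), panel.ids)
        coords, _ = pcoa(d, 1)
        axis1 = coords["PCo1"].to_numpy()
        is_p2 = panel.panel_label == "panel2"
        observed = abs(axis1[is_p2].mean() - axis1[~is_p2].mean())
        rng = np.random.default_rng(1)
        perm = [
            abs(axis1[lab].mean() - axis1[~lab].mean())
            for lab in (rng.permutation(is_p2) for _ in range(500))
        ]
        p = (np.sum(np.asarray(perm) >= observed) + 1) / 501
        assert p > 0.01
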