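"""Segmentation, LASSO cofactor selection, and the four joint mapping models.

The scan's F-tests are checked against a brute-force least-squares oracle:
explicit full and reduced design matrices, residual sums of squares from
``numpy.linalg.lstsq``, ranks from ``numpy.linalg.matrix_rank``, and the
F distribution from scipy — an independent path from the Frisch-Waugh
implementation in the package.
"""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from nampower import GeneticMap
from nampower.designs import NamPopulation
from nampower.mapping import (
    CofactorSet,
    ModelSpec,
    scan,
    segment_genome,
    select_cofactors_m1,
    select_cofactors_m2,
    effect_table,
)
from nampower.traits import TraitArchitecture, genotypic_values


# ---------------------------------------------------------------------------
# oracle
# ---------------------------------------------------------------------------

def _oracle_ftest(y, base_cols, marker_cols):
    """Full-vs-reduced ANOVA by explicit OLS, independent of the scan path."""
    B = np.column_stack(base_cols)
    X = np.column_stack(base_cols + marker_cols)
    rank_b = np.linalg.matrix_rank(B)
    rank_x = np.linalg.matrix_rank(X)

    def rss(M):
        beta, *_ = np.linalg.lstsq(M, y, rcond=None)
        r = y - M @ beta
        return float(r @ r)

    rss_b, rss_x = rss(B), rss(X)
    df_num = rank_x - rank_b
    df_den = len(y) - rank_x
    if df_num == 0 or df_den <= 0:
        return None
    F = ((rss_b - rss_x) / df_num) / (rss_x / df_den)
    return float(stats.f.sf(F, df_num, df_den))


def _oracle_scan(pop, y, spec, cofactors):
    """p-values for every marker via the explicit-design oracle."""
    dosage = pop.dosage.astype(float)
    sub = pop.subpop_index
    Z = [np.asarray(sub == s, float) for s in np.unique(sub)]
    pos, chrom = pop.gmap.pos_cm, pop.gmap.chromosome

    def term_cols(j):
        col = dosage[:, j]
        if not spec.nested:
            return [col]
        cols = []
        for s in np.unique(sub):
            rows = sub == s
            if col[rows].std() > 0:
                c = np.zeros_like(col)
                c[rows] = col[rows]
                cols.append(c)
        return cols

    out = np.full(pop.n_markers, np.nan)
    for m in range(pop.n_markers):
        if dosage[:, m].std() == 0:
            continue
        admitted = [
            int(c)
            for c in cofactors.indices
            if not (chrom[c] == chrom[m] and abs(pos[c] - pos[m]) <= spec.exclusion_window_cm)
            and c != m
            and not np.array_equal(dosage[:, c], dosage[:, m])
        ]
        base = list(Z)
        for c in admitted:
            base.extend(term_cols(c))
        marker = term_cols(m)
        if not marker:
            continue
        out[m] = _oracle_ftest(y, base, marker)
    return out


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

def _toy_pop(n_sub=3, per_sub=15, m=12, seed=0):
    rng = np.random.default_rng(seed)
    gmap = GeneticMap.uniform({"1": 30.0, "2": 20.0}, m)
    dosage = rng.integers(0, 3, size=(n_sub * per_sub, m)).astype(np.int8)
    return NamPopulation(
        dosage, np.repeat(np.arange(n_sub), per_sub), [f"f{i}" for i in range(n_sub)],
        "BC-NAM", gmap,
    )


@pytest.fixture
def toy():
    pop = _toy_pop()
    rng = np.random.default_rng(1)
    y = pop.dosage[:, 3] * 1.5 + rng.normal(size=pop.n_individuals)
    return pop, y


# ---------------------------------------------------------------------------
# tests
# ---------------------------------------------------------------------------

class TestSegmentGenome:
    def test_half_open_bins(self):
        gmap = GeneticMap(
            pd.DataFrame(
                {
                    "marker_id": list("abcde"),
                    "chromosome": "1",
                    "pos_bp": range(5),
                    "pos_cm": [0.0, 1.4, 1.5, 3.0, 4.0],
                }
            )
        )
        seg = segment_genome(gmap, 1.5)
        assert seg.tolist() == [0, 0, 1, 2, 2]  # 1.5 cM falls in the second bin

    def test_partition_preserves_marker_count(self, two_chrom_map):
        seg = segment_genome(two_chrom_map)
        assert seg.size == two_chrom_map.n_markers
        # segments never span chromosomes
        df = pd.DataFrame({"seg": seg, "chrom": two_chrom_map.chromosome})
        assert (df.groupby("seg")["chrom"].nunique() == 1).all()


class TestScanAgainstOracle:
    @pytest.mark.parametrize("model_id", ["S1", "S2", "J1", "J2"])
    def test_pvalues_match_bruteforce_ols(self, toy, model_id):
        pop, y = toy
        if model_id in ("J1", "J2"):
            seg = segment_genome(pop.gmap)
            cof = CofactorSet(np.array([1, 7, 10]), "M1", seg[[1, 7, 10]])
            spec = ModelSpec(model_id, "M1")
        else:
            cof = CofactorSet(np.empty(0, int), "none", np.empty(0, int))
            spec = ModelSpec(model_id)
        res = scan(pop, y, spec, cof if spec.uses_cofactors else None)
        oracle = _oracle_scan(pop, y, spec, cof)
        both = res.tested & np.isfinite(oracle)
        assert both.sum() >= 10
        np.testing.assert_allclose(res.p_values[both], oracle[both], atol=1e-10, rtol=1e-8)

    def test_single_subpop_single_marker_equals_classical_anova(self):
        rng = np.random.default_rng(5)
        gmap = GeneticMap.uniform({"1": 10.0}, 1)
        dosage = rng.integers(0, 3, size=(30, 1)).astype(np.int8)
        pop = NamPopulation(dosage, np.zeros(30, int), ["f"], "BC-NAM", gmap)
        y = dosage[:, 0] * 0.8 + rng.normal(size=30)
        res = scan(pop, y, ModelSpec("S2"))
        x = dosage[:, 0].astype(float)
        p = _oracle_ftest(y, [np.ones(30)], [x])
        assert res.p_values[0] == pytest.approx(p, abs=1e-12)

    def test_s1_equals_s2_with_one_subpopulation(self):
        pop = _toy_pop(n_sub=1, per_sub=40, seed=6)
        y = np.random.default_rng(7).normal(size=40) + pop.dosage[:, 2]
        p1 = scan(pop, y, ModelSpec("S1")).p_values
        p2 = scan(pop, y, ModelSpec("S2")).p_values
        np.testing.assert_allclose(p1, p2, rtol=1e-10, atol=1e-14)

    @pytest.mark.parametrize("pair", [("J1", "S1"), ("J2", "S2")])
    def test_empty_cofactor_set_reproduces_single_marker_model(self, toy, pair):
        pop, y = toy
        jm, sm = pair
        empty = CofactorSet(np.empty(0, int), "M1", np.empty(0, int))
        pj = scan(pop, y, ModelSpec(jm, "M1"), empty).p_values
        ps = scan(pop, y, ModelSpec(sm)).p_values
        np.testing.assert_array_equal(pj, ps)

    def test_null_pvalues_are_uniform(self):
        pop = _toy_pop(n_sub=4, per_sub=50, m=400, seed=8)
        y = np.random.default_rng(9).normal(size=pop.n_individuals)
        res = scan(pop, y, ModelSpec("S2"))
        p = res.p_values[res.tested]
        assert stats.kstest(p, "uniform").pvalue > 0.01

    def test_monomorphic_marker_flagged_untested(self):
        pop = _toy_pop(seed=10)
        pop.dosage[:, 4] = 2
        y = np.random.default_rng(11).normal(size=pop.n_individuals)
        res = scan(pop, y, ModelSpec("S2"))
        assert not res.table.loc[4, "tested"]
        assert np.isnan(res.table.loc[4, "p_value"])

    def test_duplicate_cofactor_column_is_aliased_not_fatal(self, toy):
        pop, y = toy
        # cofactor identical to a far-away marker: column duplicated in full model
        pop = NamPopulation(
            np.column_stack([pop.dosage, pop.dosage[:, 0]]).astype(np.int8),
            pop.subpop_index,
            pop.subpop_founder,
            pop.design_tag,
            GeneticMap.uniform({"1": 30.0, "2": 20.0, "3": 5.0}, pop.n_markers + 1),
        )
        seg = segment_genome(pop.gmap)
        cof = CofactorSet(np.array([pop.n_markers - 1]), "M1", seg[[pop.n_markers - 1]])
        res = scan(pop, y, ModelSpec("J2", "M1"), cof)
        assert res.table.loc[0, "tested"]
        oracle = _oracle_scan(pop, y, ModelSpec("J2", "M1"), cof)
        assert res.table.loc[0, "p_value"] == pytest.approx(oracle[0], abs=1e-10)


class TestCofactorSelection:
    def test_null_trait_selects_nothing_usually(self, tiny_bc_pop):
        _, pop = tiny_bc_pop
        counts = []
        for rep in range(10):
            y = np.random.default_rng(100 + rep).normal(size=pop.n_individuals)
            counts.append(len(select_cofactors_m1(pop, y, rng=rep)))
        assert np.median(counts) == 0

    def test_strong_qtl_segment_is_selected(self, tiny_bc_pop):
        _, pop = tiny_bc_pop
        seg = segment_genome(pop.gmap)
        qtl = 57
        hits = 0
        for rep in range(10):
            rng = np.random.default_rng(200 + rep)
            y = pop.dosage[:, qtl] * 5.0 + rng.normal(size=pop.n_individuals)
            cof = select_cofactors_m1(pop, y, rng=rng)
            # accept the QTL's segment or an immediately adjacent one (tight LD)
            hits += np.isin(cof.segments, [seg[qtl] - 1, seg[qtl], seg[qtl] + 1]).any()
        assert hits >= 9

    def test_m2_stays_within_m1_segments(self, tiny_bc_pop):
        _, pop = tiny_bc_pop
        rng = np.random.default_rng(33)
        y = pop.dosage[:, 20] * 3.0 + rng.normal(size=pop.n_individuals)
        m1 = select_cofactors_m1(pop, y, rng=34)
        m2 = select_cofactors_m2(m1, pop, y, rng=35)
        seg = segment_genome(pop.gmap)
        assert np.isin(seg[m2.indices], m1.segments).all()

    def test_empty_m1_gives_empty_m2(self, tiny_bc_pop):
        _, pop = tiny_bc_pop
        empty = CofactorSet(np.empty(0, int), "M1", np.empty(0, int))
        y = np.zeros(pop.n_individuals)
        assert len(select_cofactors_m2(empty, pop, y)) == 0

    def test_too_few_individuals_for_cv(self):
        pop = _toy_pop(n_sub=1, per_sub=5, seed=12)
        with pytest.raises(ValueError, match="10"):
            select_cofactors_m1(pop, np.zeros(5), rng=13)


class TestEffectTable:
    def test_noise_free_single_qtl_recovers_true_effect(self):
        pop = _toy_pop(n_sub=2, per_sub=25, m=8, seed=14)
        arch = TraitArchitecture(qtl_indices=[3], effects=[6.0], effect_allele=[1])
        y = genotypic_values(pop, arch)
        res = scan(pop, y, ModelSpec("S2"))
        tab = effect_table(res, arch)
        assert tab["estimated_effect"].iloc[0] == pytest.approx(6.0, abs=1e-8)
        # flipped effect allele: estimate flips with it
        arch0 = TraitArchitecture(qtl_indices=[3], effects=[6.0], effect_allele=[0])
        y0 = genotypic_values(pop, arch0)
        tab0 = effect_table(scan(pop, y0, ModelSpec("S2")), arch0)
        assert tab0["estimated_effect"].iloc[0] == pytest.approx(6.0, abs=1e-8)

    def test_nested_model_reports_per_subpopulation_effects(self):
        pop = _toy_pop(n_sub=3, per_sub=20, m=6, seed=15)
        pop.dosage[pop.subpop_index == 0, 2] = 2  # monomorphic in subpop 0
        arch = TraitArchitecture(qtl_indices=[2], effects=[4.0], effect_allele=[1])
        y = genotypic_values(pop, arch)
        res = scan(pop, y, ModelSpec("S1"))
        per_sub = res.table.loc[2, "effects_by_subpop"]
        assert len(per_sub) == 2  # only the two segregating subpopulations
        np.testing.assert_allclose(per_sub, 4.0, atol=1e-8)
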