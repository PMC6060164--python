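import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import spearmanr

import tegdist as td

from conftest import make_clinical, make_expr


def toy_pair():
    tumors = make_expr([[8.0], [4.0]], sample_ids=["T1"], gene_ids=["g1", "g2"],
                       is_tumor=True)
    normals = make_expr([[2.0, 8.0], [4.0, 4.0]], sample_ids=["N1", "N2"],
                        gene_ids=["g1", "g2"])
    return tumors, normals, td.GeneSet("s", ("g1", "g2"))


class TestMeanExpressionDistance:
    def test_hand_evaluated_formula(self):
        tumors, normals, gs = toy_pair()
        s = td.mean_expression_distance(tumors, normals, gs, pseudocount=0.0)
        # per-gene RMS log2 differences: (sqrt(2), 0) -> med = sqrt(2)/2
        assert s.med.iloc[0] == pytest.approx(np.sqrt(2) / 2, abs=1e-9)
        assert (s.n_genes, s.p_normals, s.q_tumors) == (2, 2, 1)

    def test_zero_distance_for_identical_profiles(self):
        tumors = make_expr([[4.0], [16.0]], sample_ids=["T1"], is_tumor=True)
        normals = make_expr([[4.0], [16.0]], sample_ids=["N1"])
        s = td.mean_expression_distance(tumors, normals,
                                        td.GeneSet("s", ("g0", "g1")), 0.0)
        assert s.med.iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_global_scaling_invariance(self):
        rng = np.random.default_rng(0)
        for trial in range(10):
            c = float(rng.uniform(0.1, 50))
            tv = rng.uniform(1, 100, size=(6, 4))
            nv = rng.uniform(1, 100, size=(6, 3))
            gs = td.GeneSet("s", tuple(f"g{i}" for i in range(6)))
            s1 = td.mean_expression_distance(
                make_expr(tv, is_tumor=True), make_expr(nv), gs, 0.0)
            s2 = td.mean_expression_distance(
                make_expr(tv * c, is_tumor=True), make_expr(nv * c), gs, 0.0)
            np.testing.assert_allclose(s1.med, s2.med, atol=1e-10)

    def test_single_normal_reduces_to_mean_absolute_log2_diff(self):
        rng = np.random.default_rng(1)
        tv = rng.uniform(1, 100, size=(5, 3))
        nv = rng.uniform(1, 100, size=(5, 1))
        gs = td.GeneSet("s", tuple(f"g{i}" for i in range(5)))
        s = td.mean_expression_distance(make_expr(tv, is_tumor=True),
                                        make_expr(nv), gs, 0.0)
        expected = np.abs(np.log2(tv) - np.log2(nv)).mean(axis=0)
        np.testing.assert_allclose(s.med.to_numpy(), expected, atol=1e-10)

    def test_missing_genes_dropped_with_adjusted_n(self):
        tumors, normals, _ = toy_pair()
        gs = td.GeneSet("s", ("g1", "g2", "absent"))
        with pytest.warns(UserWarning, match="missing"):
            s = td.mean_expression_distance(tumors, normals, gs, 0.0)
        assert s.n_genes == 2

    def test_empty_intersection_rejected(self):
        tumors, normals, _ = toy_pair()
        with pytest.raises(ValueError, match="no gene"):
            td.mean_expression_distance(tumors, normals,
                                        td.GeneSet("s", ("zz",)), 0.0)

    def test_log_scale_input_used_as_is(self):
        tumors, normals, gs = toy_pair()
        lt = td.log2_transform(tumors, 0.0)
        ln = td.log2_transform(normals, 0.0)
        s_lin = td.mean_expression_distance(tumors, normals, gs, 0.0)
        s_log = td.mean_expression_distance(lt, ln, gs, pseudocount=0.0)
        np.testing.assert_allclose(s_lin.med, s_log.med, atol=1e-12)

    def test_recovers_true_risk_on_simulation(self, sim_cohort, planted_gene_set):
        normals = sim_cohort["normals"].subset_samples(
            [s for s in sim_cohort["normals"].sample_ids if s.startswith("liver")])
        s = td.mean_expression_distance(sim_cohort["tumors"], normals,
                                        planted_gene_set, 1.0)
        truth = sim_cohort["truth"].true_linear_predictor.loc[s.med.index]
        rho, _ = spearmanr(s.med.to_numpy(), truth.to_numpy())
        assert rho >= 0.9


@settings(deadline=None, derandomize=True, max_examples=20)
@given(st.integers(min_value=4, max_value=40), st.integers(min_value=2, max_value=4))
def test_assign_groups_balanced_sizes(q, n_groups):
    rng = np.random.default_rng(q)
    med = pd.Series(rng.uniform(size=q), index=[f"t{i:02d}" for i in range(q)])
    scores = td.DistanceScores(med=med, gene_set_name="s", n_genes=1,
                               p_normals=1, q_tumors=q, pseudocount=0.0)
    g = td.assign_groups(scores, n_groups=n_groups)
    sizes = g.labels.value_counts()
    assert sizes.max() - sizes.min() <= 1
    assert sizes.sum() == q


class TestAssignGroups:
    def make_scores(self, meds, ids=None):
        ids = ids or [f"t{i}" for i in range(len(meds))]
        return td.DistanceScores(pd.Series(meds, index=ids, dtype=float),
                                 "s", 1, 1, len(meds), 0.0)

    def test_even_split_ordering(self):
        g = td.assign_groups(self.make_scores([0.6, 0.1, 0.5, 0.2, 0.4, 0.3]), 3)
        assert list(g.labels.sort_index().index) == [f"t{i}" for i in range(6)]
        assert g.labels["t1"] == "small" and g.labels["t0"] == "large"
        assert g.labels.value_counts().to_dict() == {"small": 2, "middle": 2,
                                                     "large": 2}

    def test_remainder_goes_to_earliest_groups(self):
        g = td.assign_groups(self.make_scores(list(range(7))), 3)
        sizes = g.labels.value_counts()
        assert (sizes["small"], sizes["middle"], sizes["large"]) == (3, 2, 2)

    def test_all_tied_uses_id_tiebreak_and_flags(self):
        g = td.assign_groups(self.make_scores([1.0] * 6), 3)
        assert g.tie_flag
        sizes = g.labels.value_counts()
        assert sizes.max() == sizes.min() == 2
        assert g.labels["t0"] == "small"  # id order breaks ties

    def test_too_few_groups_rejected(self):
        with pytest.raises(ValueError):
            td.assign_groups(self.make_scores([1, 2, 3]), 1)


class TestEvaluate:
    def test_null_hazard_concordance_covers_half(self):
        cfg = td.SimConfig(n_tissues=3, samples_per_tissue=5, n_genes=200,
                           n_planted_tegs=20, n_tumors=120, hazard_coef=0.0,
                           seed=21)
        normals, truth = td.simulate_multitissue(cfg)
        tumors, clin, _, truth = td.simulate_tumor_cohort(cfg, normals, truth)
        liver = normals.subset_samples(
            [s for s in normals.sample_ids if s.startswith("liver")])
        scores = td.mean_expression_distance(
            tumors, liver, td.GeneSet("p", tuple(truth.planted_teg_ids)), 1.0)
        groups = td.assign_groups(scores)
        t = clin.data["os_time_days"]
        m = td.evaluate_distance_prognosis(scores, groups, clin,
                                           list(np.quantile(t, [0.25, 0.5])))
        assert m.concordance.ci_low <= 0.5 <= m.concordance.ci_high

    def test_strong_hazard_orders_km_curves(self, sim_cohort, planted_gene_set):
        normals = sim_cohort["normals"].subset_samples(
            [s for s in sim_cohort["normals"].sample_ids if s.startswith("liver")])
        scores = td.mean_expression_distance(sim_cohort["tumors"], normals,
                                             planted_gene_set, 1.0)
        groups = td.assign_groups(scores)
        clin = sim_cohort["clinical"]
        t = clin.data["os_time_days"]
        median_fu = float(np.median(t))
        m = td.evaluate_distance_prognosis(scores, groups, clin,
                                           list(np.quantile(t, [0.25, 0.5])))
        s = {g: m.km_by_group[g].survival_at(median_fu)
             for g in ("small", "middle", "large")}
        assert s["small"] > s["middle"] > s["large"]
        assert m.logrank.p < 0.01
        assert m.concordance.c > 0.7

    def test_missing_clinical_ids_rejected(self):
        med = pd.Series([1.0, 2.0, 3.0], index=["a", "b", "zz"])
        scores = td.DistanceScores(med, "s", 1, 1, 3, 0.0)
        groups = td.assign_groups(scores, 3)
        clin = make_clinical(["a", "b"], [10, 20], [1, 1])
        with pytest.raises(ValueError, match="zz"):
            td.evaluate_distance_prognosis(scores, groups, clin, [15.0])


class TestClinicalAssociation:
    @pytest.fixture()
    def assoc(self, sim_cohort, planted_gene_set):
        normals = sim_cohort["normals"].subset_samples(
            [s for s in sim_cohort["normals"].sample_ids if s.startswith("liver")])
        scores = td.mean_expression_distance(sim_cohort["tumors"], normals,
                                             planted_gene_set, 1.0)
        groups = td.assign_groups(scores)
        return td.clinical_association(groups, sim_cohort["clinical"])

    def test_row_percentages_sum_to_100(self, assoc):
        for row in assoc:
            if row.percentages is not None and not np.isnan(row.percentages[0]):
                assert sum(row.percentages) == pytest.approx(100.0, abs=0.11)

    def test_categorical_counts_match_crosstab(self, assoc, sim_cohort):
        dead = [r for r in assoc if r.variable == "vital_status"
                and r.level == "dead"]
        assert len(dead) == 1
        assert sum(dead[0].counts) == int(
            sim_cohort["clinical"].data["os_event"].sum())

    def test_continuous_rows_have_mean_sd_and_kruskal(self, assoc):
        cont = [r for r in assoc if r.variable == "age"]
        assert len(cont) == 1
        assert len(cont[0].means) == 3
        assert 0 <= cont[0].p_value <= 1

    def test_printed_table_percentages(self):
        # worked example: AFP and vital-status rows with known counts
        assert td.row_percentages([91, 67, 43]) == [45.3, 33.3, 21.4]
        assert td.row_percentages([7, 30, 40]) == [9.1, 39.0, 51.9]
        assert td.row_percentages([31, 44, 55]) == [23.8, 33.8, 42.3]
        assert td.row_percentages([10, 10, 10]) == [33.3, 33.3, 33.3]

    def test_association_detects_planted_covariate_links(self, assoc):
        by_var = {r.variable: r for r in assoc}
        # stage and vascular invasion were planted to track the distance
        assert by_var["stage"].p_value < 0.01
        assert by_var["vascular_invasion"].p_value < 0.01
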