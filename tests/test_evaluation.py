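"""Z-test, -log10 transform, LOPO robustness and the herb network."""

import math

import networkx as nx
import numpy as np
import pytest

from cefminer.evaluation import (
    UndefinedTestError,
    build_herb_network,
    leave_one_patient_out,
    neglog10,
    rank_herbs,
    reconstruct_group_counts,
    two_proportion_ztest,
)
from cefminer.metrics import CEFCandidate
from cefminer.records import HerbVocabulary, ValidationError

from .conftest import make_table

# Published summary rows of a lung-cancer herbal case study: level-1 support,
# CEF-group EP, non-CEF-group EP, and the printed two-sided P value, over
# 419 analysis records with 93 positives in total.
CASE_STUDY_ROWS = [
    (0.021, 0.778, 0.210, 0.000),
    (0.041, 0.588, 0.206, 0.002),
    (0.043, 0.611, 0.204, 0.000),
    (0.050, 0.524, 0.206, 0.004),
    (0.084, 0.429, 0.203, 0.009),
    (0.036, 0.533, 0.210, 0.013),
    (0.041, 0.588, 0.206, 0.002),
    (0.041, 0.588, 0.206, 0.002),
    (0.041, 0.588, 0.206, 0.002),
]


class TestTwoProportionZTest:
    def test_unpooled_reproduces_case_study_p_values(self):
        for s1, ep1, ep0, p_printed in CASE_STUDY_ROWS:
            k1, n1, k0, n0 = reconstruct_group_counts(s1, ep1, ep0, 419, 93)
            res = two_proportion_ztest(k1, n1, k0, n0)
            assert round(res.p_two_sided, 3) == p_printed

    def test_fifteen_core_herb_combination_p_value(self):
        # 4 records (3 positive) against the remaining 415 (90 positive)
        res = two_proportion_ztest(3, 4, 90, 415)
        assert round(res.p_two_sided, 3) == 0.014

    def test_equal_proportions(self):
        res = two_proportion_ztest(5, 10, 50, 100)
        assert res.z == 0.0
        assert res.p_two_sided == pytest.approx(1.0)

    def test_symmetry_under_group_swap(self):
        a = two_proportion_ztest(8, 15, 85, 404)
        b = two_proportion_ztest(85, 404, 8, 15)
        assert a.z == pytest.approx(-b.z)
        assert a.p_two_sided == pytest.approx(b.p_two_sided)

    def test_degenerate_proportions_rejected(self):
        with pytest.raises(UndefinedTestError):
            two_proportion_ztest(0, 10, 0, 20)
        with pytest.raises(ValidationError):
            two_proportion_ztest(5, 4, 0, 20)

    def test_matches_statsmodels_wald(self):
        """Independent cross-check of the unpooled form."""
        sm = pytest.importorskip("statsmodels.stats.proportion")
        for k1, n1, k0, n0 in [(3, 4, 90, 415), (8, 15, 85, 404), (11, 21, 82, 398)]:
            res = two_proportion_ztest(k1, n1, k0, n0)
            z_sm, p_sm = sm.test_proportions_2indep(
                k1, n1, k0, n0, method="wald", compare="diff", correction=False
            )[:2]
            assert res.z == pytest.approx(z_sm, rel=1e-6)
            assert res.p_two_sided == pytest.approx(p_sm, rel=1e-6)

    def test_pooled_type_one_error_calibrated_where_unpooled_inflates(self):
        """At n1=20 the Wald form is anti-conservative; pooled calibrates."""
        rng = np.random.default_rng(0)
        reps = 4000
        k1 = rng.binomial(20, 0.22, reps)
        k0 = rng.binomial(400, 0.22, reps)
        rej_u = rej_p = 0
        for a, b in zip(k1, k0):
            rej_u += two_proportion_ztest(int(a), 20, int(b), 400).p_two_sided < 0.05
            rej_p += (
                two_proportion_ztest(int(a), 20, int(b), 400, pooled=True).p_two_sided
                < 0.05
            )
        assert rej_p / reps < rej_u / reps


class TestNegLog10:
    def test_threshold_identity(self):
        assert round(neglog10(0.05), 3) == 1.301

    @pytest.mark.parametrize("p, expected", [(1.0, 0.0), (0.001, 3.0)])
    def test_values(self, p, expected):
        assert neglog10(p) == pytest.approx(expected)

    def test_zero_capped_with_warning(self):
        with pytest.warns(RuntimeWarning):
            assert neglog10(0.0) == 16.0


class TestReconstruction:
    def test_positives_sum_enforced(self):
        with pytest.raises(ValidationError):
            reconstruct_group_counts(0.021, 0.778, 0.210, 419, 90)

    def test_case_study_counts(self):
        k1, n1, k0, n0 = reconstruct_group_counts(0.036, 0.533, 0.210, 419, 93)
        assert (k1, n1, k0, n0) == (8, 15, 85, 404)


class TestLOPO:
    def _table(self):
        X = np.zeros((12, 3), dtype=np.uint8)
        X[:4, :2] = 1          # CEF group records, patients a/b
        X[4:, 2] = 1
        y = [1, 1, 1, 0] + [1, 0, 0, 0, 1, 0, 0, 0]
        pids = ["a", "a", "b", "b", "c", "c", "d", "d", "e", "e", "f", "f"]
        return make_table(X, y, pids)

    def test_one_holdout_per_patient(self):
        t = self._table()
        lopo = leave_one_patient_out(t, CEFCandidate.from_indices([0, 1], 3))
        assert len(lopo.table) == 6
        s = lopo.summary()
        assert s["ep1_min"] <= s["ep1_mean"] <= s["ep1_max"]
        assert s["neglog_p_min"] <= s["neglog_p_mean"] <= s["neglog_p_max"]

    def test_removing_unrelated_patient_keeps_ep1(self):
        t = self._table()
        lopo = leave_one_patient_out(t, CEFCandidate.from_indices([0, 1], 3))
        full_ep1 = 3 / 4
        row = lopo.table[lopo.table.patient_id == "e"].iloc[0]
        assert row.ep1 == pytest.approx(full_ep1)

    def test_symmetric_patients_identical_summaries(self):
        X = np.zeros((4, 2), dtype=np.uint8)
        X[:2, 0] = 1
        X[2:, 1] = 1
        t = make_table(X, [1, 1, 0, 0], ["a", "b", "a", "b"])
        lopo = leave_one_patient_out(t, CEFCandidate.from_indices([0], 2))
        eps = lopo.table[["ep0", "ep1"]].to_numpy()
        assert np.allclose(eps[0], eps[1])

    def test_holdout_emptying_group_flagged_not_fatal(self):
        X = np.zeros((6, 2), dtype=np.uint8)
        X[:2, 0] = 1
        X[2:, 1] = 1
        y = [1, 0, 1, 0, 0, 1]
        t = make_table(X, y, ["a", "a", "b", "b", "c", "c"])
        lopo = leave_one_patient_out(t, CEFCandidate.from_indices([0], 2))
        assert lopo.n_undefined == 1  # removing patient a empties the group
        assert lopo.table["defined"].sum() == 2

    def test_ranges_contain_full_data_values_on_synthetic_cohorts(self):
        """LOPO perturbs mildly: full-data EPs fall inside holdout ranges."""
        import cefminer as cm
        from cefminer.evaluation import two_proportion_ztest
        from cefminer.metrics import split_groups

        inside = 0
        total = 0
        for seed in range(6):
            cfg = cm.tiny_config(
                seed=seed, n_patients=25, m=10,
                planted_cefs=(cm.PlantedCEF((0, 1), 0.4, 0.6),),
            )
            t = cm.generate_analysis_table(cfg)
            cand = CEFCandidate.from_indices([0, 1], 10)
            sp = split_groups(cand, t, 1.0)
            if sp.n1 == 0 or sp.n0 == 0:
                continue
            lopo = leave_one_patient_out(t, cand)
            s = lopo.summary()
            total += 1
            inside += (
                s["ep1_min"] - 1e-12 <= sp.ep1 <= s["ep1_max"] + 1e-12
                and s["ep0_min"] - 1e-12 <= sp.ep0 <= s["ep0_max"] + 1e-12
            )
        assert total >= 4 and inside / total >= 0.95


class TestHerbNetwork:
    def test_degrees_from_shared_prescriptions(self):
        X = np.array([[1, 1, 0], [0, 1, 1]], dtype=np.uint8)
        G = build_herb_network(X)
        assert G.degree(0) == 1 and G.degree(1) == 2 and G.degree(2) == 1

    def test_single_prescription_complete_graph(self):
        X = np.ones((1, 5), dtype=np.uint8)
        G = build_herb_network(X)
        assert nx.is_isomorphic(G, nx.complete_graph(5))

    def test_weights_match_brute_force_pair_counts(self):
        rng = np.random.default_rng(5)
        X = (rng.random((30, 8)) < 0.4).astype(np.uint8)
        G = build_herb_network(X)
        for u in range(8):
            for v in range(u + 1, 8):
                brute = int(np.sum(X[:, u] & X[:, v]))
                if brute >= 1:
                    assert G.edges[u, v]["weight"] == brute
                else:
                    assert not G.has_edge(u, v)

    def test_threshold_prunes_weak_edges(self):
        X = np.array([[1, 1, 0], [1, 1, 0], [1, 0, 1]], dtype=np.uint8)
        G = build_herb_network(X, threshold=2)
        assert G.has_edge(0, 1) and not G.has_edge(0, 2)

    def test_patient_frequency_attribute(self):
        X = np.array([[1, 0], [1, 0], [0, 1]], dtype=np.uint8)
        G = build_herb_network(X, patient_ids=np.array(["a", "a", "b"]))
        assert G.nodes[0]["patient_freq"] == 1
        assert G.nodes[0]["record_freq"] == 2


class TestRankHerbs:
    def test_frequency_breaks_degree_ties(self):
        vocab = HerbVocabulary(("a", "b", "c"))
        X = np.array([[1, 1, 0], [0, 1, 1], [0, 1, 1]], dtype=np.uint8)
        G = build_herb_network(X)
        df = rank_herbs(G, vocab)
        # a and c tie on degree (1); c is more frequent, so ranks ahead
        row = df.set_index("herb")
        assert row.loc["b", "degree_rank"] == 1
        assert row.loc["c", "degree_rank"] == 2
        assert row.loc["a", "degree_rank"] == 3

    def test_ranks_are_permutations(self):
        rng = np.random.default_rng(2)
        X = (rng.random((25, 9)) < 0.4).astype(np.uint8)
        G = build_herb_network(X, patient_ids=np.array([f"p{i%7}" for i in range(25)]))
        df = rank_herbs(G)
        n = len(df)
        for col in ("degree_rank", "record_freq_rank", "patient_freq_rank"):
            assert sorted(df[col]) == list(range(1, n + 1))

    def test_single_node(self):
        G = nx.Graph()
        G.add_node(0, record_freq=3)
        df = rank_herbs(G)
        assert df.iloc[0]["degree_rank"] == 1
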