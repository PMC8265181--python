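import numpy as np
import pytest
from scipy import stats

from peaks2func import (
    DataError,
    EnrichmentConfig,
    FixtureSpec,
    OmicsQuery,
    PathwayEntry,
    PathwayLibrary,
    combine_fisher,
    combine_stouffer,
    generate_complementary_peak_lists,
    generate_compound_db,
    generate_pathway_library,
    joint_pathway_analysis,
    load_adduct_rules,
    meta_analysis_pathway_level,
    meta_analysis_peak_pooling,
    mummichog_enrich,
)


class TestCombineFisher:
    def test_two_equal_p_closed_form(self):
        x2, p = combine_fisher([0.05, 0.05])
        assert x2 == pytest.approx(-4 * np.log(0.05), abs=1e-10)
        # df-4 survival: exp(-x/2) (1 + x/2)
        assert p == pytest.approx(np.exp(-x2 / 2) * (1 + x2 / 2), abs=1e-12)
        assert p == pytest.approx(0.0174787, abs=1e-6)

    def test_all_ones_give_one(self):
        assert combine_fisher([1.0, 1.0]) == (0.0, 1.0)

    def test_single_p_identity(self):
        _, p = combine_fisher([0.3])
        assert p == pytest.approx(0.3, abs=1e-12)

    def test_zero_input_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="clamped"):
            _, p = combine_fisher([0.0, 0.5])
        assert 0 <= p < 1e-12 or p >= 0

    def test_evidence_accumulates_on_copies_of_informative_p(self):
        # replicated evidence strengthens the combined call when the
        # inputs are informative (small p); near-null inputs dilute
        for p0 in (0.001, 0.01, 0.05, 0.1, 0.2):
            for k in (2, 3, 5):
                _, pc = combine_fisher([p0] * k)
                assert pc <= p0 + 1e-12

    def test_monotone_and_permutation_invariant(self):
        _, pa = combine_fisher([0.2, 0.6, 0.9])
        _, pb = combine_fisher([0.9, 0.2, 0.6])
        assert pa == pb
        _, pc = combine_fisher([0.1, 0.6, 0.9])
        assert pc <= pa


class TestCombineStouffer:
    def test_equal_weights_closed_form(self):
        z, p = combine_stouffer([0.05, 0.05])
        assert z == pytest.approx(np.sqrt(2) * stats.norm.isf(0.05), abs=1e-8)
        assert p == pytest.approx(stats.norm.sf(z), abs=1e-12)
        assert p == pytest.approx(0.0100046, abs=1e-6)

    def test_one_hot_weights_return_input(self):
        _, p = combine_stouffer([0.3, 0.9], [1.0, 0.0])
        assert p == pytest.approx(0.3, abs=1e-12)

    def test_weighted_example(self):
        z, p = combine_stouffer([0.01, 0.5], [0.8, 0.2])
        assert z == pytest.approx(0.8 * stats.norm.isf(0.01) / np.sqrt(0.68), abs=1e-8)
        assert p == pytest.approx(0.0120, abs=1e-4)

    def test_scale_invariant_in_weights(self):
        _, p1 = combine_stouffer([0.05, 0.2], [0.7, 0.3])
        _, p2 = combine_stouffer([0.05, 0.2], [7.0, 3.0])
        assert p1 == pytest.approx(p2, rel=1e-12)

    def test_monotone_in_inputs(self):
        _, pa = combine_stouffer([0.2, 0.6])
        _, pb = combine_stouffer([0.1, 0.6])
        assert pb <= pa

    def test_degenerate_weights_rejected(self):
        with pytest.raises(DataError):
            combine_stouffer([0.1, 0.2], [0.0, 0.0])


def make_joint_library():
    # one pathway with 8 genes / 2 compounds, one gene-only, one compound-only
    return PathwayLibrary(
        pathways=[
            PathwayEntry("J1", "mixed", frozenset({"c1", "c2"}),
                         frozenset({f"g{i}" for i in range(8)})),
            PathwayEntry("J2", "genes", frozenset(), frozenset({"g8", "g9"})),
            PathwayEntry("J3", "cpds", frozenset({"c3", "c4"}), frozenset()),
        ]
    )


class TestJointPathwayAnalysis:
    def test_pathway_level_weights_follow_member_counts(self):
        lib = make_joint_library()
        query = OmicsQuery(
            gene_hits={"g0", "g1"}, metabolite_hits={"c1"},
            n_genes_universe=10, n_metabolites_universe=4,
        )
        res = joint_pathway_analysis(query, lib, method="stouffer_pathway")
        row = dict(zip(res.pathway_ids, zip(res.w_gene, res.w_met)))
        assert row["J1"] == (pytest.approx(0.8), pytest.approx(0.2))

    def test_pathway_weights_reproduce_stouffer_example(self):
        # p_gene = 0.01, p_met = 0.5 at weights (0.8, 0.2) -> ~0.0120
        lib = make_joint_library()
        query = OmicsQuery(
            gene_hits={"g0"}, metabolite_hits={"c1"},
            n_genes_universe=10, n_metabolites_universe=4,
        )
        res = joint_pathway_analysis(query, lib, method="stouffer_pathway")
        i = res.pathway_ids.index("J1")
        _, expected = combine_stouffer([res.p_gene[i], res.p_met[i]], [0.8, 0.2])
        assert res.p_combined[i] == pytest.approx(expected, rel=1e-12)

    def test_single_omics_pathways_use_other_p_directly(self):
        lib = make_joint_library()
        query = OmicsQuery(
            gene_hits={"g8"}, metabolite_hits={"c3"},
            n_genes_universe=10, n_metabolites_universe=4,
        )
        res = joint_pathway_analysis(query, lib, method="fisher")
        got = dict(zip(res.pathway_ids, res.p_combined))
        pg = dict(zip(res.pathway_ids, res.p_gene))
        pm = dict(zip(res.pathway_ids, res.p_met))
        assert got["J2"] == pytest.approx(pg["J2"])
        assert got["J3"] == pytest.approx(pm["J3"])

    def test_gene_only_mode_returns_gene_p(self):
        lib = make_joint_library()
        query = OmicsQuery(
            gene_hits={"g0", "g8"}, metabolite_hits={"c1"},
            n_genes_universe=10, n_metabolites_universe=4,
        )
        res = joint_pathway_analysis(query, lib, method="fisher", library_mode="gene_only")
        np.testing.assert_allclose(res.p_combined, res.p_gene)

    def test_fisher_and_overall_stouffer_rank_alike_when_omics_agree(self):
        # mirror-symmetric memberships and hits make p_gene == p_met per
        # pathway; with G == C any symmetric monotone combiner then
        # induces the same pathway ranking
        rng = np.random.default_rng(0)
        pathways = []
        for i in range(20):
            members = rng.choice(50, int(rng.integers(5, 12)), replace=False)
            genes = frozenset(f"g{j}" for j in members)
            cpds = frozenset(f"c{j}" for j in members)
            pathways.append(PathwayEntry(f"P{i:02d}", f"p{i}", cpds, genes))
        lib = PathwayLibrary(pathways=pathways)
        query = OmicsQuery(
            gene_hits={f"g{j}" for j in range(12)},
            metabolite_hits={f"c{j}" for j in range(12)},
            n_genes_universe=50, n_metabolites_universe=50,
        )
        rf = joint_pathway_analysis(query, lib, method="fisher")
        rs = joint_pathway_analysis(query, lib, method="stouffer_overall")
        np.testing.assert_allclose(rf.p_gene, rf.p_met)
        assert rf.pathway_ids == rs.pathway_ids

    def test_empty_query_rejected(self):
        with pytest.raises(DataError, match="empty"):
            joint_pathway_analysis(
                OmicsQuery(set(), set(), 10, 10), make_joint_library()
            )


def enrich_datasets(seeds, n_active=1, effect=2.0):
    out = []
    rules = load_adduct_rules(mode="positive")
    for s in seeds:
        spec = FixtureSpec(seed=s, n_active_pathways=n_active, effect_size=effect)
        db = generate_compound_db(spec)
        lib = generate_pathway_library(db, spec)
        from peaks2func import generate_peak_table, rank_features

        table, _ = generate_peak_table(db, lib, spec)
        out.append(
            mummichog_enrich(rank_features(table), db, lib, rules,
                             EnrichmentConfig(seed=s))
        )
    return out


class TestMetaPathwayLevel:
    def test_fisher_integration_matches_combiner(self):
        r1, r2 = enrich_datasets([21, 21])
        meta = meta_analysis_pathway_level([r1, r2], method="fisher")
        m1, m2 = r1.gamma_p_by_id(), r2.gamma_p_by_id()
        for pid, p_int in zip(meta.pathway_ids, meta.p_integrated):
            _, expected = combine_fisher([max(m1[pid], 1e-300), max(m2[pid], 1e-300)])
            assert p_int == pytest.approx(expected, rel=1e-6, abs=1e-12)

    def test_venn_flags_reflect_per_dataset_significance(self):
        r1, r2 = enrich_datasets([22, 23])
        meta = meta_analysis_pathway_level([r1, r2], alpha=0.05)
        m1, m2 = r1.gamma_p_by_id(), r2.gamma_p_by_id()
        for i, pid in enumerate(meta.pathway_ids):
            assert meta.venn[i, 0] == (m1.get(pid, 1.0) <= 0.05 and pid in m1)
            assert meta.venn[i, 1] == (m2.get(pid, 1.0) <= 0.05 and pid in m2)

    def test_missing_pathway_contributes_p_one(self):
        r1, r2 = enrich_datasets([24, 25])
        # restrict dataset 2 to a subset of pathways
        r2.pathway_ids = r2.pathway_ids[:5]
        r2.pathway_names = r2.pathway_names[:5]
        r2.gamma_p = r2.gamma_p[:5]
        meta = meta_analysis_pathway_level([r1, r2], method="fisher")
        m1 = r1.gamma_p_by_id()
        present2 = set(r2.pathway_ids)
        for i, pid in enumerate(meta.pathway_ids):
            if pid not in present2:
                assert meta.missing[i, 1]
                assert meta.dataset_p[i, 1] == 1.0
                # Fisher with a p=1 partner cannot beat the dataset-1 p
                assert meta.p_integrated[i] >= m1[pid] - 1e-12

    def test_fewer_than_two_datasets_rejected(self):
        (r1,) = enrich_datasets([26])
        with pytest.raises(DataError, match="2 datasets"):
            meta_analysis_pathway_level([r1])


class TestMetaPeakPooling:
    def test_pooling_unions_complementary_coverage(self):
        spec = FixtureSpec(seed=31)
        db = generate_compound_db(spec)
        lib = generate_pathway_library(db, spec)
        pos, neg, truth = generate_complementary_peak_lists(db, lib, spec)
        cfg = EnrichmentConfig(seed=3)
        pos_rules = load_adduct_rules(mode="positive")
        neg_rules = load_adduct_rules(mode="negative")
        pooled = meta_analysis_peak_pooling([pos, neg], db, lib,
                                            [pos_rules, neg_rules], cfg)
        single = mummichog_enrich(pos, db, lib, pos_rules, cfg)
        act = truth["active_pathways"][0]
        hits_pooled = dict(zip(pooled.pathway_ids, pooled.hits_sig))[act]
        hits_single = dict(zip(single.pathway_ids, single.hits_sig)).get(act, 0)
        assert hits_pooled > hits_single

    def test_pooling_a_list_with_itself_is_idempotent_in_hits(self):
        spec = FixtureSpec(seed=32)
        db = generate_compound_db(spec)
        lib = generate_pathway_library(db, spec)
        pos, neg, _ = generate_complementary_peak_lists(db, lib, spec)
        cfg = EnrichmentConfig(seed=3)
        pos_rules = load_adduct_rules(mode="positive")
        import copy

        from peaks2func import AdductRule

        pos2 = copy.deepcopy(pos)
        pos2.mode = "negative"  # distinct mode tag, same peaks
        retagged = [
            AdductRule(r.name, r.nmer, r.mass_shift, r.charge, "negative")
            for r in pos_rules
        ]
        pooled = meta_analysis_peak_pooling([pos, pos2], db, lib,
                                            [pos_rules, retagged], cfg)
        single = mummichog_enrich(pos, db, lib, pos_rules, cfg)
        hp = dict(zip(pooled.pathway_ids, pooled.hits_sig))
        hs = dict(zip(single.pathway_ids, single.hits_sig))
        assert hp == hs

    def test_conflicting_duplicate_triples_rejected(self):
        spec = FixtureSpec(seed=33)
        db = generate_compound_db(spec)
        lib = generate_pathway_library(db, spec)
        pos, neg, _ = generate_complementary_peak_lists(db, lib, spec)
        rules = load_adduct_rules(mode="positive")
        with pytest.raises(DataError, match="duplicate"):
            meta_analysis_peak_pooling([pos, pos], db, lib, [rules, rules],
                                       EnrichmentConfig(seed=1))
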