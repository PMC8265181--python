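import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from peaks2func import (
    AdductRule,
    CompoundDB,
    CompoundRecord,
    DataError,
    annotate_peaks,
    build_empirical_compounds,
    load_adduct_rules,
    match_names,
    normalize_compound_name,
    predicted_mz,
)
from conftest import GLUCOSE_MASS, M_PLUS_2H, M_PLUS_H, M_PLUS_NA, make_peaks


class TestPredictedMz:
    @pytest.mark.parametrize(
        "rule, expected",
        [
            (M_PLUS_H, 181.070666),
            (AdductRule("M+2H", 1, 2.014552, 2, "positive"), 91.038971),
            (AdductRule("M", 1, 0.0, 1, "positive"), GLUCOSE_MASS),
        ],
    )
    def test_hand_computed_glucose_adducts(self, rule, expected):
        assert predicted_mz(GLUCOSE_MASS, rule) == pytest.approx(expected, abs=1e-6)

    def test_dimer_uses_nmer(self):
        rule = AdductRule("2M+H", 2, 1.007276, 1, "positive")
        assert predicted_mz(100.0, rule) == pytest.approx(201.007276)

    def test_negative_mass_rejected(self):
        with pytest.raises(DataError):
            predicted_mz(-1.0, M_PLUS_H)


def brute_force_annotation(peaks, db, rules, ppm_tol, drop_currency=True):
    """Independent oracle: enumerate every (peak, compound, rule) triple."""
    out = set()
    for i, mz in enumerate(peaks.mz):
        for rec in db.records:
            if drop_currency and rec.compound_id in db.currency_ids:
                continue
            for rule in rules:
                if rule.mode != peaks.mode:
                    continue
                pred = (rule.nmer * rec.monoisotopic_mass + rule.mass_shift) / abs(rule.charge)
                if pred > 0 and abs(mz - pred) / pred * 1e6 <= ppm_tol:
                    out.add((i, rec.compound_id, rule.name))
    return out


class TestAnnotatePeaks:
    def test_glucose_mh_hit_within_tolerance(self, small_db):
        peaks = make_peaks([181.070666])
        ann = annotate_peaks(peaks, small_db, [M_PLUS_H], ppm_tol=5.0)
        assert len(ann.matches) == 1
        assert ann.matches[0].compound_id == "glc"
        assert ann.matches[0].ppm_error == pytest.approx(0.0, abs=0.01)

    def test_51_ppm_off_is_no_match(self, small_db):
        peaks = make_peaks([181.080000])
        ann = annotate_peaks(peaks, small_db, [M_PLUS_H], ppm_tol=5.0)
        assert ann.matches == []

    def test_currency_compounds_suppressed_by_default(self, small_db):
        water_mh = predicted_mz(18.010565, M_PLUS_H)
        peaks = make_peaks([water_mh])
        assert annotate_peaks(peaks, small_db, [M_PLUS_H]).annotated_compounds == set()
        kept = annotate_peaks(peaks, small_db, [M_PLUS_H], drop_currency=False)
        assert kept.annotated_compounds == {"h2o"}

    def test_no_rules_for_mode_rejected(self, small_db):
        peaks = make_peaks([181.07], mode="negative")
        with pytest.raises(DataError, match="negative"):
            annotate_peaks(peaks, small_db, [M_PLUS_H])

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_oracle_on_random_databases(self, seed):
        rng = np.random.default_rng(seed)
        n_cpd = int(rng.integers(10, 50))
        masses = rng.uniform(80, 800, size=n_cpd)
        db = CompoundDB(
            records=[CompoundRecord(f"C{i}", m, f"c{i}") for i, m in enumerate(masses)],
            currency_ids={f"C{i}" for i in rng.choice(n_cpd, 2, replace=False)},
        )
        rules = load_adduct_rules(mode="positive")
        # peaks: some near predicted values, some random
        near = [
            predicted_mz(masses[j], rules[k]) * (1 + rng.normal(0, 3e-6))
            for j, k in zip(rng.integers(0, n_cpd, 40), rng.integers(0, len(rules), 40))
        ]
        random = rng.uniform(80, 900, size=40).tolist()
        peaks = make_peaks(near + random)
        ann = annotate_peaks(peaks, db, rules, ppm_tol=5.0)
        got = {(m.feature_index, m.compound_id, m.adduct_name) for m in ann.matches}
        assert got == brute_force_annotation(peaks, db, rules, 5.0)

    def test_match_count_monotone_in_ppm_tolerance(self, small_db):
        rng = np.random.default_rng(1)
        peaks = make_peaks(181.070666 * (1 + rng.normal(0, 5e-6, size=50)))
        counts = [
            len(annotate_peaks(peaks, small_db, [M_PLUS_H], ppm_tol=tol).matches)
            for tol in (1.0, 2.0, 5.0, 10.0, 20.0)
        ]
        assert counts == sorted(counts)


class TestEmpiricalCompounds:
    def test_coeluting_adducts_merge(self, small_db):
        peaks = make_peaks(
            [predicted_mz(GLUCOSE_MASS, M_PLUS_H), predicted_mz(GLUCOSE_MASS, M_PLUS_NA)],
            rt=[35.1, 35.3],
        )
        ann = annotate_peaks(peaks, small_db, [M_PLUS_H, M_PLUS_NA])
        ecs = build_empirical_compounds(ann, peaks, rt_tol=5.0)
        assert len(ecs) == 1
        assert len(ecs[0].matches) == 2

    def test_distant_rt_clusters_split(self, small_db):
        peaks = make_peaks(
            [predicted_mz(GLUCOSE_MASS, M_PLUS_H), predicted_mz(GLUCOSE_MASS, M_PLUS_NA)],
            rt=[35.0, 300.0],
        )
        ann = annotate_peaks(peaks, small_db, [M_PLUS_H, M_PLUS_NA])
        assert len(build_empirical_compounds(ann, peaks, rt_tol=5.0)) == 2

    def test_single_linkage_chains_through_intermediate_peak(self, small_db):
        mzs = [
            predicted_mz(GLUCOSE_MASS, M_PLUS_H),
            predicted_mz(GLUCOSE_MASS, M_PLUS_NA),
            predicted_mz(GLUCOSE_MASS, M_PLUS_2H),
        ]
        peaks = make_peaks(mzs, rt=[10.0, 14.0, 18.0])
        ann = annotate_peaks(peaks, small_db, [M_PLUS_H, M_PLUS_NA, M_PLUS_2H])
        # 10 <-> 18 gap is 8 > 5, but both link to 14: one component
        ecs = build_empirical_compounds(ann, peaks, rt_tol=5.0)
        assert len(ecs) == 1 and len(ecs[0].matches) == 3

    def test_output_partitions_the_match_set(self, small_db):
        rng = np.random.default_rng(2)
        peaks = make_peaks(
            181.070666 * (1 + rng.normal(0, 2e-6, size=20)),
            rt=rng.uniform(0, 600, size=20),
        )
        ann = annotate_peaks(peaks, small_db, [M_PLUS_H])
        ecs = build_empirical_compounds(ann, peaks, rt_tol=10.0)
        all_members = [
            (m.feature_index, m.compound_id, m.adduct_name)
            for ec in ecs for m in ec.matches
        ]
        assert len(all_members) == len(ann.matches)
        assert set(all_members) == {
            (m.feature_index, m.compound_id, m.adduct_name) for m in ann.matches
        }

    def test_missing_rt_directs_to_v1(self, small_db):
        peaks = make_peaks([181.070666])
        ann = annotate_peaks(peaks, small_db, [M_PLUS_H])
        with pytest.raises(DataError, match="v1"):
            build_empirical_compounds(ann, peaks, rt_tol=5.0)


class TestNameNormalization:
    @pytest.mark.parametrize(
        "raw, expected",
        [
            ("PC (16:0/18:1)", "pc(16:0/18:1)"),
            ("PC(16:0/18:1)", "pc(16:0/18:1)"),
            ("pc 16:0/18:1", "pc(16:0/18:1)"),
            ("PC 16:0_18:1", "pc(16:0_18:1)"),
            ("Glucose", "glucose"),
            ("PC [16:0/18:1]", "pc(16:0/18:1)"),
            ("  alpha  D  glucose ", "alpha d glucose"),
        ],
    )
    def test_canonical_forms(self, raw, expected):
        assert normalize_compound_name(raw) == expected

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.text(min_size=1, max_size=40))
    def test_idempotent(self, name):
        once = normalize_compound_name(name)
        assert normalize_compound_name(once) == once


class TestMatchNames:
    def test_priority_exact_then_synonym_then_normalized(self, small_db):
        out = match_names(["Glucose", "Dextrose", "glucose", "unobtainium"], small_db)
        assert out[0] == ("Glucose", "glc", "exact")
        assert out[1] == ("Dextrose", "glc", "synonym")
        assert out[2] == ("glucose", "glc", "normalized")
        assert out[3] == ("unobtainium", None, "none")

    def test_lipid_variant_matches_normalized_primary(self):
        db = CompoundDB(records=[CompoundRecord("pc1", 759.578, "PC(16:0/18:1)")])
        out = match_names(["PC (16:0/18:1)"], db)
        assert out[0][1:] == ("pc1", "normalized")
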