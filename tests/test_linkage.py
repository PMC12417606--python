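"""Fellegi-Sunter linkage: comparators, weights, assignment, kappa."""

import itertools
import math
from datetime import date

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from prevlink.linkage import (
    FieldSpec,
    LinkageConfig,
    assign_bijective,
    block,
    cohens_kappa,
    dedupe_patients,
    field_similarity,
    link,
    linkage_accuracy,
    match_rates,
    pair_weight,
)
from prevlink.simulate import simulate

from conftest import clinical_only_config

DOB_SPEC = FieldSpec("dob", "date_tolerant", m=0.95, u=0.001)
EXACT_SPEC = FieldSpec("commune", "exact", m=0.9, u=0.05)
ORD_SPEC = FieldSpec("ses", "ordinal", m=0.8, u=0.2)


class TestComparators:
    def test_exact_identical_and_different(self):
        assert field_similarity("Temuco", "Temuco", EXACT_SPEC) == 1.0
        assert field_similarity("Temuco", "Villarrica", EXACT_SPEC) == 0.0

    def test_exact_against_commune_set(self):
        assert field_similarity("B", ("A", "B"), EXACT_SPEC) == 1.0
        assert field_similarity("C", ("A", "B"), EXACT_SPEC) == 0.0

    def test_ordinal_adjacent_bands(self):
        # adjacent among the 6 ranked fee bands -> 1 - 1/5
        assert field_similarity("Free", "1.15-11.50", ORD_SPEC) == pytest.approx(0.8)
        assert field_similarity("Free", ">115.02", ORD_SPEC) == pytest.approx(0.0)
        assert field_similarity("Missing", "Free", ORD_SPEC) == 0.0

    def test_date_tolerant_against_transposition_oracle(self):
        # independent oracle over a small grid of date pairs
        days = [date(1990, m, d) for m in (3, 7) for d in (3, 7, 12, 25)]
        for a, b in itertools.product(days, days):
            transposed = (
                a.year == b.year and a.day == b.month and a.month == b.day and a != b
            )
            expected = 1.0 if a == b else (0.8 if transposed else 0.0)
            assert field_similarity(a.isoformat(), b.isoformat(), DOB_SPEC) == expected

    def test_missing_scores_zero(self):
        assert field_similarity(None, "1990-03-07", DOB_SPEC) == 0.0
        assert field_similarity(float("nan"), "x", EXACT_SPEC) == 0.0


class TestPairWeight:
    def test_single_field_full_agreement(self):
        spec = FieldSpec("f", "exact", m=0.9, u=0.1)
        assert pair_weight({"f": 1.0}, [spec]) == pytest.approx(math.log2(9))

    def test_uninformative_field_near_zero_weight(self):
        # m == u is rejected as configuration error; m -> u gives weight -> 0
        spec = FieldSpec("f", "exact", m=0.5000001, u=0.5)
        assert abs(pair_weight({"f": 0.3}, [spec])) < 1e-5

    def test_m_not_greater_than_u_rejected(self):
        with pytest.raises(ValueError):
            FieldSpec("f", "exact", m=0.2, u=0.2)
        with pytest.raises(ValueError):
            FieldSpec("f", "exact", m=0.1, u=0.2)

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=3, max_size=3))
    def test_matches_sum_of_logs_oracle(self, sims):
        specs = [
            FieldSpec("a", "exact", m=0.9, u=0.01),
            FieldSpec("b", "exact", m=0.7, u=0.3),
            FieldSpec("c", "exact", m=0.95, u=0.5),
        ]
        similarities = dict(zip("abc", sims))
        oracle = sum(
            s * math.log2(sp.m / sp.u) + (1 - s) * math.log2((1 - sp.m) / (1 - sp.u))
            for s, sp in zip(sims, specs)
        )
        assert pair_weight(similarities, specs) == pytest.approx(oracle, abs=1e-12)


class TestBlocking:
    def _students(self, rows):
        return pd.DataFrame(rows, columns=["student_id", "sex", "dob"])

    def _patients(self, rows):
        return pd.DataFrame(rows, columns=["patient_id", "sex", "dob"])

    def test_disjoint_dobs_no_candidates(self):
        s = self._students([("s1", "M", "2010-01-01")])
        p = self._patients([("p1", "M", "2012-05-05")])
        assert len(block(s, p)) == 0

    def test_shared_sex_dob_one_candidate(self):
        s = self._students([("s1", "M", "2010-01-01")])
        p = self._patients([("p1", "M", "2010-01-01"), ("p2", "F", "2010-01-01")])
        cand = block(s, p)
        assert len(cand) == 1
        assert cand["patient_id"].iloc[0] == "p1"

    def test_no_noise_candidates_cover_all_true_matches(self):
        cfg = clinical_only_config(
            seed=13, n=20000,
            field_error_rates={"dob": 0.0, "commune": 0.0, "ses": 0.0},
        )
        students, patients, truth = simulate(cfg)
        flagged = students[students["asd_flag"]]
        unique, _ = dedupe_patients(patients)
        cand = block(flagged, unique)
        got = set(zip(cand["student_id"], cand["patient_id"]))
        # exhaustive enumeration oracle over the truth table
        lat = unique.set_index("patient_id")["latent_person_id"]
        true_pairs = {
            (lat[pid], pid) for pid in unique["patient_id"]
            if lat[pid] in set(flagged["student_id"])
        }
        assert true_pairs <= got


class TestAssignment:
    def _scored(self, triples):
        return pd.DataFrame(triples, columns=["student_id", "patient_id", "weight"])

    def test_greedy_example(self):
        scored = self._scored([("A", "X", 5.0), ("A", "Y", 4.0), ("B", "Y", 3.0)])
        ms = assign_bijective(scored, threshold=0.0)
        got = set(zip(ms.pairs["student_id"], ms.pairs["patient_id"]))
        # brute-force over bijective subsets in greedy order
        assert got == {("A", "X"), ("B", "Y")}

    def test_all_below_threshold_empty(self):
        scored = self._scored([("A", "X", 5.0)])
        ms = assign_bijective(scored, threshold=10.0)
        assert ms.pairs.empty
        assert ms.unmatched_students == ["A"]
        assert ms.unmatched_patients == ["X"]

    def test_bijectivity(self):
        scored = self._scored(
            [(s, p, w) for (s, p), w in zip(
                itertools.product("ABCD", "WXYZ"), np.linspace(10, 2, 16))]
        )
        ms = assign_bijective(scored, threshold=0.0)
        assert ms.pairs["student_id"].is_unique
        assert ms.pairs["patient_id"].is_unique

    def test_order_invariance(self):
        scored = self._scored(
            [("A", "X", 5.0), ("B", "X", 5.0), ("A", "Y", 5.0), ("B", "Y", 3.0)]
        )
        base = assign_bijective(scored, threshold=0.0).pairs
        for seed in range(5):
            shuffled = scored.sample(frac=1, random_state=seed).reset_index(drop=True)
            again = assign_bijective(shuffled, threshold=0.0).pairs
            pd.testing.assert_frame_equal(
                base.reset_index(drop=True), again.reset_index(drop=True)
            )

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(0)
        scored = self._scored(
            [(f"s{i}", f"p{j}", float(rng.normal(5, 3)))
             for i in range(8) for j in range(8)]
        )
        sizes = [len(assign_bijective(scored, t).pairs) for t in np.linspace(-5, 15, 21)]
        assert all(a >= b for a, b in zip(sizes, sizes[1:]))


class TestDedupe:
    def test_multi_commune_patient_collapses(self):
        patients = pd.DataFrame({
            "patient_id": ["p1", "p1"],
            "dob": ["2010-01-01"] * 2,
            "sex": ["M"] * 2,
            "commune": ["A", "B"],
            "latent_person_id": ["s1"] * 2,
        })
        unique, conflicts = dedupe_patients(patients)
        assert len(unique) == 1
        assert unique["communes"].iloc[0] == ("A", "B")
        assert conflicts.empty

    def test_already_unique_identity(self):
        patients = pd.DataFrame({
            "patient_id": ["p1", "p2"],
            "dob": ["2010-01-01", "2011-02-02"],
            "sex": ["M", "F"],
            "commune": ["A", "B"],
            "latent_person_id": ["s1", "s2"],
        })
        unique, _ = dedupe_patients(patients)
        assert len(unique) == 2

    def test_conflicting_dob_flagged(self):
        patients = pd.DataFrame({
            "patient_id": ["p1", "p1"],
            "dob": ["2010-01-01", "2010-01-02"],
            "sex": ["M", "M"],
            "commune": ["A", "A"],
            "latent_person_id": ["s1"] * 2,
        })
        _, conflicts = dedupe_patients(patients)
        assert list(conflicts["patient_id"]) == ["p1"]

    def test_unique_count_equals_latent_count(self):
        cfg = clinical_only_config(seed=17, n=20000, multi_commune_prob=0.3)
        _, patients, truth = simulate(cfg)
        unique, _ = dedupe_patients(patients)
        assert len(unique) == truth["in_ehr"].sum()
        assert len(patients) > len(unique)  # duplication actually occurred


class TestValidationStats:
    def test_published_match_rates(self):
        rates = match_rates(233, 488, 1376, 233 + 1132)
        assert round(rates["pct_unique_patients_matched"], 2) == 17.07
        assert round(rates["pct_school_records_matched"], 2) == 47.75

    def test_zero_and_full_match_rates(self):
        assert match_rates(0, 10, 10, 10)["pct_unique_patients_matched"] == 0.0
        assert match_rates(10, 10, 10, 10)["pct_unique_patients_matched"] == 100.0
        with pytest.raises(ValueError):
            match_rates(1, 0, 10, 10)

    def test_kappa_perfect_and_independent(self):
        assert cohens_kappa([[10, 0], [0, 30]]) == pytest.approx(1.0)
        # independence: cell counts equal to products of the margins
        assert cohens_kappa([[16, 24], [24, 36]]) == pytest.approx(0.0, abs=1e-12)

    def test_kappa_hand_formula(self):
        t = np.array([[45, 1], [1, 3]], float)
        n = t.sum()
        po = np.trace(t) / n
        pe = (t.sum(0) * t.sum(1)).sum() / n**2
        assert cohens_kappa(t) == pytest.approx((po - pe) / (1 - pe), abs=1e-12)

    def test_kappa_degenerate(self):
        with pytest.raises(ZeroDivisionError):
            cohens_kappa([[5, 0], [0, 0]])


class TestEndToEndLinkage:
    def test_no_noise_perfect_precision_recall(self):
        cfg = clinical_only_config(
            seed=19, n=20000,
            field_error_rates={"dob": 0.0, "commune": 0.0, "ses": 0.0},
            missing_commune_prob=0.0,
        )
        students, patients, truth = simulate(cfg)
        flagged = students[students["asd_flag"]]
        ms, _, _ = link(flagged, patients)
        acc = linkage_accuracy(ms, patients, truth)
        assert acc["precision"] == 1.0
        assert acc["recall"] == 1.0

    def test_grey_zone_between_bounds(self):
        cfg = clinical_only_config(seed=23, n=20000)
        students, patients, _ = simulate(cfg)
        flagged = students[students["asd_flag"]]
        config = LinkageConfig(threshold=12.0, grey_low=8.0)
        ms, grey, _ = link(flagged, patients, config)
        if len(grey):
            assert (grey["weight"] >= 8.0).all()
            assert (grey["weight"] < 12.0).all()
        assert (ms.pairs["weight"] >= 12.0).all()
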