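"""Grading logic: readers, druse classification, aggregation, agreement."""

import itertools

import numpy as np
import pytest
from hypothesis import given, strategies as st

from drusenshadow import classification as cls
from drusenshadow.classification import (
    DruseAssessment,
    DruseGrade,
    ReaderParams,
    aggregate,
    agreement,
    assess_roi,
    classify_druse,
    grades_from_assessments,
    load_reference_cohort,
    round_pct,
)
from drusenshadow.slab_projection import EnFacePair, SlabSpec


def make_pair(octa, oct_slab, device="SD840"):
    octa = np.asarray(octa, dtype=float)
    return EnFacePair(
        oct_slab=np.asarray(oct_slab, dtype=float),
        octa_slab=octa,
        masked_fraction=np.zeros_like(octa),
        spec=SlabSpec(),
        device=device,
    )


# ----------------------------------------------------------------------
# classify_druse: exhaustive truth-table check against an independent oracle
# ----------------------------------------------------------------------

def oracle_grade(sd_octa, sd_oct, ss_octa, ss_oct):
    """Plain restatement of the grading definitions, kept independent."""
    sd_class = "none" if not sd_octa else ("ambiguous" if sd_oct else "unambiguous")
    ss_class = "none" if not ss_octa else ("ambiguous" if ss_oct else "unambiguous")
    return {
        "sd_loss": sd_octa,
        "sd_class": sd_class,
        "ss_loss": ss_octa,
        "ss_class": ss_class,
        "sd_false_positive": sd_class == "ambiguous" and not ss_octa,
        "ss_false_positive": ss_class == "ambiguous" and not sd_octa,
    }


class TestClassifyDruse:
    def test_truth_table_all_joint_cases(self):
        for combo in itertools.product([False, True], repeat=4):
            sd_octa, sd_oct, ss_octa, ss_oct = combo
            grade = classify_druse(
                DruseAssessment("SD840", sd_octa, sd_oct),
                DruseAssessment("SS1050", ss_octa, ss_oct),
            )
            expected = oracle_grade(*combo)
            for key, val in expected.items():
                assert getattr(grade, key) == val, (combo, key)

    def test_masked_sd_with_clear_ss_is_sd_false_positive(self):
        g = classify_druse(
            DruseAssessment("SD840", True, True),
            DruseAssessment("SS1050", False, False),
        )
        assert g.sd_class == "ambiguous" and g.sd_false_positive
        assert not g.ss_false_positive

    def test_true_flow_void_is_unambiguous_on_both(self):
        g = classify_druse(
            DruseAssessment("SD840", True, False),
            DruseAssessment("SS1050", True, False),
        )
        assert g.sd_class == g.ss_class == "unambiguous"
        assert not g.sd_false_positive and not g.ss_false_positive

    def test_device_mismatch_rejected(self):
        with pytest.raises(ValueError):
            classify_druse(
                DruseAssessment("SS1050", True, True),
                DruseAssessment("SS1050", False, False),
            )

    def test_false_positive_needs_other_device_clear(self):
        # invariant holds over the whole truth table: FP flags are impossible
        # when the other device shows loss
        for combo in itertools.product([False, True], repeat=4):
            g = classify_druse(
                DruseAssessment("SD840", combo[0], combo[1]),
                DruseAssessment("SS1050", combo[2], combo[3]),
            )
            if g.ss_loss:
                assert not g.sd_false_positive
            if g.sd_loss:
                assert not g.ss_false_positive
            # exhaustive & exclusive classes, conservation per device
            assert (g.sd_class == "none") == (not g.sd_loss)
            assert (g.ss_class == "none") == (not g.ss_loss)


# ----------------------------------------------------------------------
# aggregation
# ----------------------------------------------------------------------

def random_grades(rng, n):
    grades = []
    for _ in range(n):
        combo = rng.integers(0, 2, size=4).astype(bool)
        grades.append(
            classify_druse(
                DruseAssessment("SD840", combo[0], combo[1]),
                DruseAssessment("SS1050", combo[2], combo[3]),
            )
        )
    return grades


class TestAggregate:
    def test_matches_brute_force_recount_on_random_cohorts(self, rng):
        for _ in range(100):
            grades = random_grades(rng, int(rng.integers(1, 40)))
            s = aggregate(grades)
            n_loss_sd = sum(g.sd_loss for g in grades)
            assert s.sd.n_loss == n_loss_sd
            assert s.sd.n_ambiguous == sum(g.sd_class == "ambiguous" for g in grades)
            assert s.sd.n_unambiguous == sum(g.sd_class == "unambiguous" for g in grades)
            assert s.sd.n_ambiguous + s.sd.n_unambiguous == s.sd.n_loss
            assert s.sd.n_false_positive == sum(g.sd_false_positive for g in grades)
            assert s.ss.n_loss == sum(g.ss_loss for g in grades)
            assert s.ss.n_ambiguous + s.ss.n_unambiguous == s.ss.n_loss
            assert s.sd.pct_loss == round_pct(n_loss_sd, len(grades))
            if n_loss_sd:
                assert s.sd.pct_ambiguous == round_pct(s.sd.n_ambiguous, n_loss_sd)
            else:
                assert s.sd.pct_ambiguous is None

    def test_single_druse_unambiguous_on_both(self):
        g = classify_druse(
            DruseAssessment("SD840", True, False),
            DruseAssessment("SS1050", True, False),
        )
        s = aggregate([g])
        assert s.sd.pct_loss == 100.0 and s.ss.pct_loss == 100.0
        assert s.sd.n_false_positive == 0 and s.ss.n_false_positive == 0

    def test_all_clear_cohort(self):
        g = classify_druse(
            DruseAssessment("SD840", False, False),
            DruseAssessment("SS1050", False, False),
        )
        s = aggregate([g] * 10)
        assert s.sd.n_loss == 0 and s.sd.pct_loss == 0.0
        assert s.sd.pct_ambiguous is None

    def test_empty_cohort_reports_absent_percentages(self):
        s = aggregate([])
        assert s.n_drusen == 0
        assert s.sd.pct_loss is None

    def test_rounding_is_half_up_to_one_decimal(self):
        assert round_pct(41, 2000) == 2.1  # 2.05 rounds up, not to even
        assert round_pct(17, 23) == 73.9
        assert round_pct(1, 3) == 33.3


# ----------------------------------------------------------------------
# reference cohort (synthetic per-druse table matching the published tallies)
# ----------------------------------------------------------------------

class TestReferenceCohort:
    def test_published_tallies_reproduced(self):
        df = load_reference_cohort()
        assert len(df) == 23
        s = aggregate(grades_from_assessments(df))
        assert (s.sd.n_loss, s.sd.pct_loss) == (17, 73.9)
        assert (s.sd.n_ambiguous, s.sd.pct_ambiguous) == (14, 82.4)
        assert (s.sd.n_unambiguous, s.sd.pct_unambiguous) == (3, 17.6)
        assert (s.sd.n_false_positive, s.sd.pct_false_positive) == (10, 58.8)
        assert (s.ss.n_loss, s.ss.pct_loss) == (7, 30.4)
        assert s.ss.n_unambiguous == 7 and s.ss.n_ambiguous == 0
        assert s.ss.n_false_positive == 0


# ----------------------------------------------------------------------
# automatic reader
# ----------------------------------------------------------------------

class TestAssessRoi:
    def test_masked_roi_over_bright_background_is_low(self):
        img = np.full((20, 20), 0.5)
        roi = np.zeros((20, 20), dtype=bool)
        roi[8:12, 8:12] = True
        octa = img.copy()
        octa[roi] = 0.0  # threshold-masked
        a = assess_roi(make_pair(octa, img), roi)
        assert a.low_octa and not a.low_oct

    def test_roi_statistically_identical_to_background_is_clear(self, rng):
        img = rng.normal(1.0, 0.05, (40, 40)).clip(0, None)
        octa = (img / img.max()).clip(0, 1)
        roi = np.zeros((40, 40), dtype=bool)
        roi[10:20, 10:20] = True
        a = assess_roi(make_pair(octa, img), roi)
        assert not a.low_octa and not a.low_oct

    def test_empty_roi_raises(self):
        img = np.ones((10, 10))
        with pytest.raises(ValueError):
            assess_roi(make_pair(img, img), np.zeros((10, 10), dtype=bool))

    def test_empty_background_raises(self):
        img = np.ones((10, 10))
        roi = np.ones((10, 10), dtype=bool)
        with pytest.raises(ValueError):
            assess_roi(make_pair(img, img), roi)

    @given(st.integers(0, 2**32 - 1))
    def test_low_call_monotone_in_k(self, seed):
        # a stricter "low" criterion (larger k) can only add low calls
        rng = np.random.default_rng(seed)
        img = rng.uniform(0.1, 1.0, (24, 24))
        octa = rng.uniform(0.0, 1.0, (24, 24))
        roi = np.zeros((24, 24), dtype=bool)
        roi[6:14, 6:14] = True
        calls = []
        for k in (0.2, 0.4, 0.6, 0.8):
            reader = ReaderParams(low_pixel_factor=k, low_area_fraction=0.35)
            calls.append(assess_roi(make_pair(octa, img), roi, reader).low_octa)
        assert calls == sorted(calls)  # False -> True transitions only

    def test_reader_parameter_validation(self):
        with pytest.raises(ValueError):
            ReaderParams(low_pixel_factor=1.5)
        with pytest.raises(ValueError):
            ReaderParams(low_area_fraction=0.0)


# ----------------------------------------------------------------------
# interreader agreement
# ----------------------------------------------------------------------

class TestAgreement:
    def test_identical_lists_perfect(self):
        pct, kappa = agreement(["a", "b", "a"], ["a", "b", "a"])
        assert pct == 100.0 and kappa == 1.0

    def test_single_label_perfect_agreement_still_kappa_one(self):
        pct, kappa = agreement([True] * 5, [True] * 5)
        assert pct == 100.0 and kappa == 1.0

    def test_45_of_46_matches(self):
        a = [True] * 30 + [False] * 16
        b = list(a)
        b[0] = False  # one disagreement
        pct, kappa = agreement(a, b)
        assert round(pct, 1) == 97.8
        assert 0.9 < kappa <= 1.0

    def test_independent_labels_give_kappa_near_zero(self, rng):
        n = 10_000
        a = rng.integers(0, 2, n)
        b = rng.integers(0, 2, n)
        _, kappa = agreement(list(a), list(b))
        assert abs(kappa) < 0.05

    def test_matches_sklearn_on_generic_lists(self, rng):
        from sklearn.metrics import cohen_kappa_score

        a = list(rng.integers(0, 3, 200))
        b = list(rng.integers(0, 3, 200))
        _, kappa = agreement(a, b)
        assert kappa == pytest.approx(cohen_kappa_score(a, b), abs=1e-12)

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            agreement([1, 2], [1])
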