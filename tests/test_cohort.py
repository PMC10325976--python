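"""Patient model, eligibility rules, and the genotype-phenotype comparisons."""

import pytest

from moyastrat import (
    ArteryInvolvement, Patient, StrokeMap, Table2x2, compare_age_at_onset,
    compare_involvement, compare_laterality, eligible_for_onset, fisher_exact,
    ischemic_burden_comparison, mann_whitney_exact, read_cohort_table,
    under_age_subset, write_cohort_table,
)


def make_patient(pid, carrier=False, onset=None, diagnosis="MMD", syndrome=None,
                 incidental=False, arteries=(), strokes=()):
    return Patient(
        patient_id=pid, diagnosis=diagnosis, syndrome=syndrome,
        incidental_diagnosis=incidental, age_at_onset_months=onset,
        rnf213_carrier=carrier,
        arteries=ArteryInvolvement(frozenset(arteries)),
        strokes=StrokeMap(frozenset(strokes)),
    )


by_carrier = lambda p: p.rnf213_carrier  # noqa: E731


class TestDomainTypes:
    def test_artery_involved_and_bilateral(self):
        art = ArteryInvolvement(frozenset({"PCA_L", "PCA_R", "MCA_L"}))
        assert art.involved("PCA") and art.bilateral("PCA")
        assert art.involved("MCA") and not art.bilateral("MCA")
        assert not art.involved("ACA")

    def test_stroke_burden_counts_slots(self):
        sm = StrokeMap(frozenset({
            "stroke_PCA_cortical_L", "stroke_MCA_subcortical_R",
            "stroke_MCA-PCA_watershed_cortical_L",
        }))
        assert sm.burden == 3
        assert sm.affected("PCA", "cortical")
        assert sm.affected("MCA-PCA_watershed", "cortical")
        assert not sm.affected("ACA", "cortical")

    def test_unknown_slot_rejected(self):
        with pytest.raises(ValueError):
            StrokeMap(frozenset({"stroke_XYZ_cortical_L"}))

    def test_cohort_tsv_round_trip(self, tmp_path):
        cohort = [
            make_patient("p1", carrier=True, onset=35.5, diagnosis="MMD",
                         arteries={"PCA_L", "PCA_R"},
                         strokes={"stroke_PCA_cortical_L"}),
            make_patient("p2", diagnosis="MMS", syndrome="NF1", incidental=True),
        ]
        path = tmp_path / "cohort.tsv"
        write_cohort_table(cohort, path)
        back = read_cohort_table(path)
        assert back == cohort


class TestEligibility:
    def test_incidental_always_excluded(self):
        p = make_patient("x", incidental=True, syndrome="NF1", diagnosis="MMS")
        assert not eligible_for_onset(p)

    def test_symptomatic_nf1_with_rnf213_excluded_in_carrier_context(self):
        p = make_patient("x", carrier=True, onset=12.0, diagnosis="MMS", syndrome="NF1")
        assert not eligible_for_onset(p, context="rnf213")
        assert not eligible_for_onset(p, context="nf1")
        assert eligible_for_onset(p, context="mmd_vs_mms")

    def test_plain_symptomatic_patient_eligible(self):
        assert eligible_for_onset(make_patient("x", onset=30.0))

    @pytest.mark.parametrize("onset, kept", [(59.9, True), (60.0, False), (None, False)])
    def test_under_age_subset_strict_boundary(self, onset, kept):
        subset = under_age_subset([make_patient("x", onset=onset)])
        assert (len(subset) == 1) == kept


class TestOnsetComparison:
    def test_matches_kernel_on_same_values(self):
        cohort = (
            [make_patient(f"c{i}", carrier=True, onset=v) for i, v in enumerate([10, 20, 30])]
            + [make_patient(f"n{i}", onset=v) for i, v in enumerate([40, 50, 60])]
        )
        res = compare_age_at_onset(cohort, by_carrier)
        assert res.p_value == pytest.approx(
            mann_whitney_exact([10, 20, 30], [40, 50, 60]).p_value
        )
        assert res.p_value == pytest.approx(0.1)
        assert res.extra["mean_a"] == pytest.approx(20.0)

    def test_exclusions_applied_before_test(self):
        cohort = (
            [make_patient(f"c{i}", carrier=True, onset=v) for i, v in enumerate([10, 20])]
            + [make_patient("excl", carrier=True, onset=5.0, syndrome="NF1", diagnosis="MMS")]
            + [make_patient("inc", carrier=True, incidental=True, diagnosis="MMD")]
            + [make_patient(f"n{i}", onset=v) for i, v in enumerate([40, 50])]
        )
        res = compare_age_at_onset(cohort, by_carrier)
        assert res.extra["n_x"] == 2  # excluded double-carrier and incidental

    def test_empty_group_is_error(self):
        cohort = [make_patient("a", onset=1.0), make_patient("b", onset=2.0)]
        with pytest.raises(ValueError, match="group_a"):
            compare_age_at_onset(cohort, by_carrier)


class TestInvolvementComparison:
    def test_identical_groups_all_p_one(self):
        art = {"ACA_L", "MCA_R"}
        cohort = (
            [make_patient(f"c{i}", carrier=True, arteries=art) for i in range(4)]
            + [make_patient(f"n{i}", arteries=art) for i in range(4)]
        )
        for r in compare_involvement(cohort, by_carrier):
            assert r.p_value == pytest.approx(1.0)

    def test_compositional_consistency_with_fisher(self):
        """Per-structure 2x2 equals a direct fisher_exact call (8/13 vs 16/71)."""
        cohort = (
            [make_patient(f"c{i}", carrier=True,
                          arteries={"PCA_L"} if i < 8 else set()) for i in range(13)]
            + [make_patient(f"n{i}",
                            arteries={"PCA_R"} if i < 16 else set()) for i in range(71)]
        )
        results = {r.label: r for r in compare_involvement(cohort, by_carrier)}
        direct = fisher_exact(Table2x2(8, 5, 16, 55))
        assert results["artery_PCA"].p_value == pytest.approx(direct.p_value, rel=1e-12)
        assert results["artery_PCA"].odds_ratio == pytest.approx(direct.odds_ratio, rel=1e-9)
        # family size = 3 arteries + 10 stroke structures
        assert results["artery_PCA"].n_comparisons == 13
        assert results["artery_PCA"].p_adjusted == pytest.approx(
            min(1.0, 13 * direct.p_value)
        )

    def test_double_carriers_excluded(self):
        cohort = (
            [make_patient(f"c{i}", carrier=True, arteries={"PCA_L"}) for i in range(5)]
            + [make_patient("dbl", carrier=True, syndrome="NF1", diagnosis="MMS",
                            arteries={"PCA_L", "PCA_R"})]
            + [make_patient(f"n{i}") for i in range(5)]
        )
        results = {r.label: r for r in compare_involvement(cohort, by_carrier)}
        assert results["artery_PCA"].extra["n_a"] == 5

    def test_empty_structure_p_one(self):
        cohort = (
            [make_patient(f"c{i}", carrier=True) for i in range(3)]
            + [make_patient(f"n{i}") for i in range(3)]
        )
        results = {r.label: r for r in compare_involvement(cohort, by_carrier)}
        assert results["artery_ACA"].p_value == 1.0


class TestLaterality:
    def test_all_bilateral_vs_all_unilateral(self):
        """5 bilateral carriers vs 5 unilateral non-carriers -> p = 2/252."""
        cohort = (
            [make_patient(f"c{i}", carrier=True, arteries={"PCA_L", "PCA_R"})
             for i in range(5)]
            + [make_patient(f"n{i}", arteries={"PCA_L"}) for i in range(5)]
        )
        res = compare_laterality(cohort, by_carrier, "PCA")
        assert res.p_value == pytest.approx(2 / 252, rel=1e-9)

    def test_identical_groups(self):
        cohort = (
            [make_patient(f"c{i}", carrier=True, arteries={"PCA_L"}) for i in range(4)]
            + [make_patient(f"n{i}", arteries={"PCA_R"}) for i in range(4)]
        )
        assert compare_laterality(cohort, by_carrier, "PCA").p_value == pytest.approx(1.0)

    def test_unknown_artery_rejected(self):
        with pytest.raises(ValueError):
            compare_laterality([make_patient("a", carrier=True), make_patient("b")],
                               by_carrier, "ICA")


class TestIschemicBurden:
    def test_all_zero_burdens(self):
        cohort = ([make_patient(f"c{i}", carrier=True) for i in range(3)]
                  + [make_patient(f"n{i}") for i in range(3)])
        assert ischemic_burden_comparison(cohort, by_carrier).p_value == pytest.approx(1.0)

    def test_separated_burdens_enumeration(self):
        slots = [
            "stroke_PCA_cortical_L", "stroke_PCA_cortical_R",
            "stroke_MCA_cortical_L", "stroke_MCA_cortical_R",
            "stroke_ACA_cortical_L", "stroke_ACA_cortical_R",
            "stroke_MCA_subcortical_L",
        ]
        burdens_a, burdens_b = [0, 0, 1], [5, 6, 7]
        cohort = (
            [make_patient(f"c{i}", carrier=True, strokes=set(slots[:k]))
             for i, k in enumerate(burdens_a)]
            + [make_patient(f"n{i}", strokes=set(slots[:k]))
               for i, k in enumerate(burdens_b)]
        )
        res = ischemic_burden_comparison(cohort, by_carrier)
        assert res.p_value == pytest.approx(0.1)
        assert res.extra["mean_b"] == pytest.approx(6.0)
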