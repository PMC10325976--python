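"""EM mixture fitting, cutpoints, tier rule, group comparison, ellipses."""

import numpy as np
import pytest
from scipy.stats import chi2

from moyastrat import (
    AnnotatedVariant, classify_tier, classify_variants, compare_score_groups,
    confidence_ellipse, derive_cutpoint, fit_gmm_em, fit_score_model,
)
from moyastrat.mixture import DegenerateDataError, InsufficientDataError


class TestFitGmmEm:
    def test_recovers_generating_means(self, separated_scores):
        scores, (mu_lo, mu_hi) = separated_scores
        fit = fit_gmm_em(scores)
        assert fit.converged
        # within 3 standard errors of the generating means (se = sd/sqrt(100))
        assert abs(fit.means[0] - mu_lo) < 3 * 1.0 / 10
        assert abs(fit.means[1] - mu_hi) < 3 * 2.0 / 10

    def test_loglik_nondecreasing(self, separated_scores):
        fit = fit_gmm_em(separated_scores[0])
        assert np.all(np.diff(fit.loglik_path) >= -1e-9)

    def test_identical_observations_rejected(self):
        with pytest.raises(DegenerateDataError):
            fit_gmm_em([5.0, 5.0, 5.0, 5.0])

    def test_too_few_observations_rejected(self):
        with pytest.raises(InsufficientDataError):
            fit_gmm_em([1.0, 2.0, 3.0])

    def test_mirror_symmetry(self):
        rng = np.random.default_rng(3)
        half = np.sort(rng.normal(5.0, 1.0, 80))
        scores = np.concatenate([-half, half])
        fit = fit_gmm_em(scores)
        assert fit.means[0] == pytest.approx(-fit.means[1], abs=1e-6)

    def test_deterministic_no_rng(self, separated_scores):
        a = fit_gmm_em(separated_scores[0])
        b = fit_gmm_em(separated_scores[0])
        assert np.array_equal(a.means, b.means)
        assert a.n_iterations == b.n_iterations

    def test_weights_and_responsibilities_normalized(self, separated_scores):
        fit = fit_gmm_em(separated_scores[0])
        assert fit.weights.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all((fit.responsibilities >= 0) & (fit.responsibilities <= 1))
        assert fit.means[0] <= fit.means[1]

    def test_scale_equivariance(self, separated_scores):
        """Affine map a*x+b (a>0) maps means and cutpoint; tiers unchanged."""
        scores = separated_scores[0]
        a, b = 2.5, -7.0
        f1 = fit_score_model(scores)
        f2 = fit_score_model(a * scores + b)
        assert f2.means == pytest.approx(a * f1.means + b, rel=1e-5)
        assert f2.cutpoint == pytest.approx(a * f1.cutpoint + b, rel=1e-7)
        flags1 = scores >= f1.cutpoint
        flags2 = (a * scores + b) >= f2.cutpoint
        assert np.array_equal(flags1, flags2)


class TestCutpoint:
    def test_well_separated_clusters(self):
        scores = [10.0, 11.0, 12.0, 30.0, 31.0, 32.0]
        fit = fit_gmm_em(scores)
        assert derive_cutpoint(fit, scores) == 30.0

    def test_singleton_outlier_is_its_own_cutpoint(self):
        scores = [10.0, 10.1, 9.9, 10.2, 9.8, 10.0, 50.0]
        fit = fit_gmm_em(scores)
        cut = derive_cutpoint(fit, scores)
        assert cut == 50.0

    def test_no_high_assignment_warns_and_returns_none(self, separated_scores):
        fit = fit_gmm_em(separated_scores[0])
        with pytest.warns(UserWarning, match="cutpoint undefined"):
            # scoring only low-cluster values leaves the high cluster empty
            assert derive_cutpoint(fit, [8.0, 9.0, 10.0]) is None

    def test_requires_convergence(self, separated_scores):
        fit = fit_gmm_em(separated_scores[0])
        fit.converged = False
        with pytest.raises(ValueError):
            derive_cutpoint(fit, separated_scores[0])


class TestClassifyTier:
    TRUTH_TABLE = [
        ("high", "high", "deleterious"),
        ("high", "low", "possibly_deleterious"),
        ("high", "missing", "possibly_deleterious"),
        ("low", "high", "possibly_deleterious"),
        ("low", "low", "benign"),
        ("low", "missing", "benign"),  # CADD-only classification precedent
    ]

    @pytest.mark.parametrize("cadd_flag, vipur_flag, tier", TRUTH_TABLE)
    def test_truth_table(self, cadd_flag, vipur_flag, tier):
        assert classify_tier(cadd_flag, vipur_flag) == tier

    def test_missing_cadd_is_error(self):
        with pytest.raises(ValueError):
            classify_tier("missing", "high")


class TestClassifyVariants:
    @pytest.fixture
    def fits(self):
        # clusters separated so the smallest MAP-high observation is exactly
        # the published-style threshold (24 CADD, 0.46 VIPUR)
        rng = np.random.default_rng(0)
        cadd = np.concatenate([rng.uniform(10, 18, 120),
                               np.r_[24.0, rng.uniform(25, 33, 119)]])
        vipur = np.concatenate([rng.uniform(0.05, 0.30, 120),
                                np.r_[0.46, rng.uniform(0.55, 0.95, 119)]])
        return fit_score_model(cadd), fit_score_model(vipur)

    def test_boundary_inclusive_and_missing_vipur(self, fits):
        cadd_fit, vipur_fit = fits
        assert cadd_fit.cutpoint == 24.0 and vipur_fit.cutpoint == 0.46
        variants = [
            AnnotatedVariant(variant_id="exact_boundary", gene="G", cadd=24.0, vipur=0.46),
            AnnotatedVariant(variant_id="below_above", gene="G", cadd=23.99, vipur=0.47),
            AnnotatedVariant(variant_id="low_cadd_no_vipur", gene="G", cadd=12.8, vipur=None),
        ]
        calls = {c.variant_id: c.tier for c in classify_variants(variants, cadd_fit, vipur_fit)}
        assert calls["exact_boundary"] == "deleterious"
        assert calls["below_above"] == "possibly_deleterious"
        assert calls["low_cadd_no_vipur"] == "benign"


class TestCompareScoreGroups:
    def _variants(self, groups):
        out = []
        for label, values in groups.items():
            for i, v in enumerate(values):
                out.append(AnnotatedVariant(
                    variant_id=f"{label}{i}", gene="G", cadd=float(v),
                    vipur=None, phenotype_label=label,
                ))
        return out

    def test_identical_groups_p_one(self):
        vs = self._variants({"MMA": [1, 2, 3], "aortic": [1, 2, 3]})
        (res,) = compare_score_groups(vs, "CADD")
        assert res.p_value == pytest.approx(1.0)

    def test_separated_groups_enumeration(self):
        vs = self._variants({"MMA": [1, 2, 3], "aortic": [10, 11, 12]})
        (res,) = compare_score_groups(vs, "CADD")
        assert res.p_value == pytest.approx(0.1)
        assert res.mean_a != res.mean_b

    def test_missing_scores_dropped_with_warning(self):
        vs = self._variants({"MMA": [1, 2, 3], "aortic": [5, 6, 7]})
        with pytest.warns(UserWarning, match="lacked a VIPUR score"):
            with pytest.raises(ValueError, match="phenotype groups"):
                compare_score_groups(vs, "VIPUR")


class TestConfidenceEllipse:
    def test_circle_centered_at_origin(self):
        theta = np.linspace(0, 2 * np.pi, 16, endpoint=False)
        pts = np.c_[np.cos(theta), np.sin(theta)] * 3.0
        e = confidence_ellipse(pts)
        assert e.mean_vector == pytest.approx([0.0, 0.0], abs=1e-9)

    def test_identity_covariance_axes(self):
        """Sample with exactly identity covariance -> both semi-axes sqrt(q95)."""
        base = np.array([[1.0, 0.0], [-1.0, 0.0], [0.0, 1.0], [0.0, -1.0]])
        pts = base * np.sqrt(3 / 2)  # scale so ddof=1 covariance is identity
        e = confidence_ellipse(pts)
        q = chi2.ppf(0.95, 2)
        assert q == pytest.approx(5.9915, abs=1e-4)
        assert e.semi_axes == pytest.approx([np.sqrt(q)] * 2, rel=1e-9)

    def test_collinear_points_degenerate(self):
        pts = [[0, 0], [1, 1], [2, 2]]
        with pytest.warns(UserWarning, match="degenerate"):
            e = confidence_ellipse(pts)
        assert e.degenerate
        assert e.semi_axes[1] == pytest.approx(0.0, abs=1e-9)

    def test_distances_to_group_mean(self):
        pts = np.array([[0.0, 0.0], [2.0, 0.0], [1.0, 3.0]])
        e = confidence_ellipse(pts)
        expected = np.linalg.norm(pts - pts.mean(axis=0), axis=1)
        assert e.distances == pytest.approx(expected)
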