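"""Power calculations: ambiguity terms, Z prediction, binomial detection."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import lpmadc as L
from lpmadc.power import (
    AmbiguityTerms,
    ambiguity_terms,
    detection_probability,
    min_cohort_for_confidence,
    predict_z,
)


def _two_component_model(mu_c, mu_t, sd, n_bins=100):
    import pandas as pd

    grid = L.BinGrid.uniform(n_bins, 0, 3e-3, visits=("V1",))
    c = grid.centers
    pc = np.exp(-0.5 * ((c - mu_c) / sd) ** 2)
    pt = np.exp(-0.5 * ((c - mu_t) / sd) ** 2)
    comps = [
        L.PMFComponent(pc / pc.sum(), "control"),
        L.PMFComponent(pt / pt.sum(), "treatment"),
    ]
    return L.LPMResults(
        grid=grid, components=comps, training_weights=pd.DataFrame(),
        loglik=0.0, loglik_history=np.asarray([]), selection_reports={},
        sufficient=True, seed=0, config=L.LPMConfig(), training_ids=[],
    )


def _fit_with_weights(model, weights):
    from lpmadc.model import TumorFitResults

    w = np.asarray(weights, dtype=float)
    return TumorFitResults(
        model=model, histogram=None, weights=w,
        weight_covariance=np.eye(2), chi2_per_df=1.0,
        expected_counts=model.P @ w, unexplained_count=0.0,
        loglik_history=np.asarray([]),
    )


class TestAmbiguityTerms:
    def test_disjoint_support_gives_one(self):
        model = _two_component_model(0.5e-3, 2.5e-3, 0.05e-3)
        fit = _fit_with_weights(model, [500.0, 500.0])
        amb = ambiguity_terms(model, [fit])
        assert amb.T_star == pytest.approx(1.0, abs=1e-6)
        assert amb.C_star == pytest.approx(1.0, abs=1e-6)

    def test_identical_pmfs_give_half(self):
        model = _two_component_model(1.0e-3, 1.0e-3, 0.3e-3)
        fit = _fit_with_weights(model, [500.0, 500.0])
        amb = ambiguity_terms(model, [fit])
        assert amb.T_star == pytest.approx(0.5, abs=1e-9)
        assert amb.C_star == pytest.approx(0.5, abs=1e-9)

    def test_matches_quadrature_oracle(self):
        mu_c, mu_t, sd = 1.0e-3, 1.8e-3, 0.3e-3
        qc, qt = 700.0, 1300.0
        model = _two_component_model(mu_c, mu_t, sd, n_bins=200)
        fit = _fit_with_weights(model, [qc, qt])
        amb = ambiguity_terms(model, [fit])
        # direct numerical integration on the same discretisation
        c = model.grid.centers
        pc = np.exp(-0.5 * ((c - mu_c) / sd) ** 2)
        pt = np.exp(-0.5 * ((c - mu_t) / sd) ** 2)
        pc, pt = pc / pc.sum(), pt / pt.sum()
        m_c, m_t = qc * pc, qt * pt
        post_t = m_t / (m_c + m_t)
        t_star = np.sum(m_t * post_t) / m_t.sum()
        c_star = np.sum(m_c * (1 - post_t)) / m_c.sum()
        assert amb.T_star == pytest.approx(t_star, rel=1e-9)
        assert amb.C_star == pytest.approx(c_star, rel=1e-9)

    def test_model_without_treatment_rejected(self, small_models):
        control, _ = small_models
        with pytest.raises(ValueError):
            ambiguity_terms(control, [])

    def test_terms_bounded(self):
        with pytest.raises(ValueError):
            AmbiguityTerms(0.0, 0.5)
        with pytest.raises(ValueError):
            AmbiguityTerms(0.5, 1.5)


class TestPredictZ:
    def test_zero_voxels_give_zero(self):
        assert predict_z(0.0, AmbiguityTerms(0.9, 0.9)) == 0.0

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        q=st.floats(min_value=0.0, max_value=1e6),
        t=st.floats(min_value=0.05, max_value=1.0),
        c=st.floats(min_value=0.05, max_value=1.0),
    )
    def test_quadrupling_voxels_doubles_z(self, q, t, c):
        amb = AmbiguityTerms(t, c)
        assert predict_z(4 * q, amb) == pytest.approx(2 * predict_z(q, amb))

    def test_less_overlap_means_more_power(self):
        q = 2000.0
        zs = [
            predict_z(q, AmbiguityTerms(t, t))
            for t in (0.6, 0.7, 0.8, 0.9, 0.999)
        ]
        assert all(b > a for a, b in zip(zs, zs[1:]))

    def test_extreme_ambiguity_clips_at_zero(self):
        # bracket negative: T* tiny, C* tiny
        assert predict_z(1000.0, AmbiguityTerms(0.05, 0.05)) == 0.0


class TestDetectionProbability:
    @pytest.mark.parametrize("n", [1, 3, 10])
    def test_degenerate_fractions(self, n):
        assert detection_probability(n, 0.0) == 0.0
        assert detection_probability(n, 1.0) == 1.0

    def test_ten_mice_twenty_percent_responders(self):
        # 1 - 0.8^10 = 0.8926: the '90% confidence at N=10' design point
        assert detection_probability(10, 0.2) == pytest.approx(
            1 - 0.8**10, abs=1e-12
        )

    def test_five_mice_half_responding_exceeds_95(self):
        assert detection_probability(5, 0.5) == pytest.approx(0.96875)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        n=st.integers(min_value=1, max_value=30),
        f=st.floats(min_value=0.0, max_value=1.0),
    )
    def test_binomial_sum_equals_closed_form(self, n, f):
        assert detection_probability(n, f) == pytest.approx(
            1 - (1 - f) ** n, abs=1e-12
        )

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            detection_probability(0, 0.5)
        with pytest.raises(ValueError):
            detection_probability(5, 1.5)


class TestMinCohort:
    def test_certain_response_needs_one_mouse(self):
        assert min_cohort_for_confidence(1.0, 0.99) == 1

    def test_half_responding_needs_five_for_95(self):
        assert min_cohort_for_confidence(0.5, 0.95) == 5
        # boundary: four mice are not enough (1 - 0.5^4 = 0.9375)
        assert detection_probability(4, 0.5) < 0.95

    def test_monotone_in_response_fraction(self):
        sizes = [
            min_cohort_for_confidence(f, 0.9)
            for f in np.linspace(0.1, 1.0, 19)
        ]
        assert all(b <= a for a, b in zip(sizes, sizes[1:]))

    def test_zero_fraction_rejected(self):
        with pytest.raises(ValueError):
            min_cohort_for_confidence(0.0, 0.9)
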