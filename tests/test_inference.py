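"""Response readouts: posteriors, decomposition, summaries, t-test."""

import numpy as np
import pytest
from scipy import stats

import lpmadc as L
from lpmadc.inference import (
    cohort_t_test,
    decompose_distribution,
    posterior_maps,
    summary_params,
)


@pytest.fixture(scope="module")
def treated_fit(small_models, small_study):
    _, full = small_models
    hists, _, _ = small_study
    h = next(x for x in hists if x.cohort == "treated")
    return full, full.fit_tumor(h)


class TestPosteriors:
    def test_classes_sum_to_one_on_support(self, treated_fit):
        model, fit = treated_fit
        post_t, post_c, supported = posterior_maps(model, fit)
        assert np.allclose(post_t[supported] + post_c[supported], 1.0)
        assert np.all((post_t[supported] >= 0) & (post_t[supported] <= 1))
        assert np.all(np.isnan(post_t[~supported]))

    def test_treatment_only_bins_have_posterior_one(self, treated_fit):
        model, fit = treated_fit
        post_t, _, supported = posterior_maps(model, fit)
        P = model.P
        only_t = (
            (P[:, model.is_treatment].sum(axis=1) > 0)
            & (P[:, ~model.is_treatment].sum(axis=1) == 0)
        )
        if fit.weights[model.is_treatment].sum() > 0 and only_t.any():
            assert np.allclose(post_t[only_t & supported], 1.0)

    def test_posterior_weighted_counts_reproduce_qt(self, treated_fit):
        # sum_bins E[H] * P(C=t | bin) equals QT at the EM fixed point
        model, fit = treated_fit
        post_t, _, supported = posterior_maps(model, fit)
        qt = np.nansum(fit.expected_counts[supported] * post_t[supported])
        assert qt == pytest.approx(fit.QT, rel=1e-6)


class TestAssessment:
    def test_zero_treatment_weights_give_null_assessment(
        self, small_models, small_study
    ):
        _, full = small_models
        hists, _, _ = small_study
        h = next(x for x in hists if x.cohort == "control")
        fit = full.fit_tumor(h)
        fit.weights[full.is_treatment] = 0.0
        a = fit.assess()
        assert a.QT == 0.0 and a.z == 0.0 and not a.responder
        assert a.p_value == pytest.approx(0.5)

    def test_conservation_qt_plus_qc(self, treated_fit):
        _, fit = treated_fit
        a = fit.assess()
        assert a.QT + a.QC == pytest.approx(
            fit.histogram.total - fit.unexplained_count, rel=1e-9
        )

    def test_sigma_matches_bootstrap(self, treated_fit):
        # nonparametric bootstrap of the voxel counts (Poisson resampling
        # per bin) against the Fisher-information standard error
        model, fit = treated_fit
        rng = np.random.default_rng(17)
        qts = []
        for _ in range(200):
            counts = rng.poisson(fit.histogram.counts)
            h = L.TumorHistogram("b", "treated", counts, model.grid, 0)
            qts.append(model.fit_tumor(h).QT)
        boot_sd = np.std(qts, ddof=1)
        a = fit.assess()
        assert a.sigma_QT == pytest.approx(boot_sd, rel=0.20)

    def test_per_tumor_independence(self, small_models, small_study):
        # a tumor's QT does not depend on which other tumors are assessed
        _, full = small_models
        hists, _, _ = small_study
        treated = [h for h in hists if h.cohort == "treated"]
        solo = full.fit_tumor(treated[0]).QT
        for other in treated[1:3]:
            full.fit_tumor(other)
        assert full.fit_tumor(treated[0]).QT == solo


class TestDecomposition:
    def test_parts_sum_to_expectation(self, treated_fit):
        model, fit = treated_fit
        affected, unaffected = decompose_distribution(model, fit)
        total = (affected + unaffected).reshape(-1, order="F")
        assert np.allclose(total, fit.expected_counts)
        assert affected.sum() == pytest.approx(fit.QT, rel=1e-9)
        assert unaffected.sum() == pytest.approx(fit.QC, rel=1e-9)

    def test_zero_treatment_weights_give_zero_affected(
        self, small_models, small_study
    ):
        _, full = small_models
        hists, _, _ = small_study
        h = next(x for x in hists if x.cohort == "control")
        fit = full.fit_tumor(h)
        fit.weights[full.is_treatment] = 0.0
        affected, _ = decompose_distribution(full, fit)
        assert np.all(affected == 0)


class TestSummaryParams:
    def test_point_mass_mean_equals_p95_equals_center(self):
        edges = np.linspace(0, 1e-3, 11)
        hist = np.zeros(10)
        hist[4] = 50
        sp = summary_params(hist, edges, voxel_vol=1.0)
        center = 0.5 * (edges[4] + edges[5])
        assert sp.mean_adc == pytest.approx(center)
        assert sp.p95_adc == pytest.approx(center)

    def test_volume_uses_voxel_volume(self):
        edges = np.linspace(0, 1e-3, 11)
        hist = np.full(10, 100.0)
        sp = summary_params(hist, edges, voxel_vol=0.25)
        assert sp.volume == pytest.approx(250.0)  # 1000 voxels at 0.25 mm^3

    def test_p95_within_one_bin_of_sort_oracle(self):
        rng = np.random.default_rng(23)
        edges = np.linspace(0, 3e-3, 41)
        hist = rng.integers(0, 40, size=40).astype(float)
        hist[hist.sum() == 0] = 1
        sp = summary_params(hist, edges, voxel_vol=1.0)
        centers = 0.5 * (edges[:-1] + edges[1:])
        sample = np.repeat(centers, hist.astype(int))
        oracle = np.percentile(sample, 95)
        assert abs(sp.p95_adc - oracle) <= edges[1] - edges[0]

    def test_zero_mass_rejected(self):
        with pytest.raises(ValueError):
            summary_params(np.zeros(5), np.linspace(0, 1, 6), 1.0)


class TestCohortTTest:
    def test_identical_groups_give_p_one(self):
        vals = [1.0, 2.0, 3.0, 4.0]
        assert cohort_t_test(vals, vals) == pytest.approx(1.0)

    def test_separated_groups_give_tiny_p(self):
        rng = np.random.default_rng(3)
        a = 0.0 + 1e-9 * rng.standard_normal(4)
        b = 1.0 + 1e-9 * rng.standard_normal(4)
        assert cohort_t_test(a, b) < 1e-10

    def test_matches_welch_formula(self):
        a = np.array([1.1, 2.3, 0.9, 1.7, 2.0])
        b = np.array([2.8, 3.1, 2.2, 3.9])
        t = (b.mean() - a.mean()) / np.sqrt(a.var(ddof=1) / 5 + b.var(ddof=1) / 4)
        va, vb = a.var(ddof=1) / 5, b.var(ddof=1) / 4
        df = (va + vb) ** 2 / (va**2 / 4 + vb**2 / 3)
        p_hand = 2 * stats.t.sf(abs(t), df)
        assert cohort_t_test(a, b) == pytest.approx(p_hand, rel=1e-12)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            cohort_t_test([1.0], [2.0, 3.0])
        with pytest.raises(ValueError):
            cohort_t_test([1.0, 1.0], [2.0, 2.0])
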