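"""Cohort simulation: weight mixing bounds, Poisson moments, TPR tables."""

import numpy as np
import pytest

import lpmadc as L
from lpmadc.simulate import SimulationSpec, build_sim_cohorts, evaluate_tpr, synthesize_histogram


@pytest.fixture(scope="module")
def pools(small_models, small_study):
    _, full = small_models
    hists, truth, _ = small_study
    ctrl = [full.fit_tumor(h) for h in hists if h.cohort == "control"]
    resp = [
        full.fit_tumor(h)
        for h in hists
        if h.cohort == "treated"
        and truth.loc[truth.tumor_id == h.tumor_id, "responder"].iloc[0]
    ]
    return full, ctrl, resp


class TestSynthesizeHistogram:
    def test_zero_deviation_same_tumor_reproduces_expectation(self, pools):
        model, ctrl, _ = pools
        base = ctrl[0]
        rng = np.random.default_rng(0)
        totals = []
        for _ in range(60):
            h, w = synthesize_histogram(model, base, base, 0.0, rng)
            assert np.allclose(w, base.weights)
            totals.append(h.total)
        expect = (model.P @ base.weights).sum()
        # sampled totals fluctuate Poisson-style around the expectation
        assert abs(np.mean(totals) - expect) < 4 * np.sqrt(expect / 60)

    def test_weights_respect_half_value_envelope(self, pools):
        model, ctrl, resp = pools
        rng = np.random.default_rng(1)
        for _ in range(100):
            a, b = resp[0], ctrl[-1]
            _, w = synthesize_histogram(model, a, b, 0.5, rng)
            lo = 0.5 * np.minimum(a.weights, b.weights)
            hi = 1.5 * np.maximum(a.weights, b.weights)
            assert np.all(w >= lo - 1e-9) and np.all(w <= hi + 1e-9)

    def test_binwise_mean_and_variance_are_poisson(self, pools):
        model, ctrl, _ = pools
        base = ctrl[1]
        rng = np.random.default_rng(2)
        draws = np.stack(
            [
                synthesize_histogram(model, base, base, 0.0, rng)[0].flat
                for _ in range(1000)
            ]
        )
        expect = model.P @ base.weights
        big = expect > 5
        mean_err = np.abs(draws.mean(axis=0)[big] - expect[big])
        var_err = np.abs(draws.var(axis=0)[big] - expect[big])
        # Monte Carlo error bands at 1000 draws
        assert np.all(mean_err < 5 * np.sqrt(expect[big] / 1000))
        assert np.all(var_err < 7 * expect[big] * np.sqrt(2.0 / 999))

    def test_excessive_deviation_rejected(self, pools):
        model, ctrl, _ = pools
        with pytest.raises(ValueError):
            synthesize_histogram(
                model, ctrl[0], ctrl[1], 0.6, np.random.default_rng(0)
            )


class TestBuildCohorts:
    def test_label_bookkeeping_exact(self, pools):
        model, ctrl, resp = pools
        spec = SimulationSpec(N=6, n=2, cohorts_per_setting=3, seed=4)
        cohorts = build_sim_cohorts(spec, model, ctrl, resp)
        treatment = [c for c in cohorts if not c.is_null]
        nulls = [c for c in cohorts if c.is_null]
        assert len(treatment) == 3 and len(nulls) == 3
        for c in treatment:
            assert len(c.tumors) == 6
            assert sum(t.responder for t in c.tumors) == 2
            assert len(c.control_reference) == 6
        for c in nulls:
            assert c.n_responders == 0

    @pytest.mark.parametrize("n", [0, 6])
    def test_all_null_and_all_responder_cohorts(self, pools, n):
        model, ctrl, resp = pools
        spec = SimulationSpec(N=6, n=n, cohorts_per_setting=1, seed=5)
        cohorts = build_sim_cohorts(spec, model, ctrl, resp, include_null=False)
        assert cohorts[0].n_responders == n

    def test_invalid_subset_rejected(self):
        with pytest.raises(ValueError):
            SimulationSpec(N=4, n=5)


@pytest.fixture(scope="module")
def table(pools):
    model, ctrl, resp = pools
    spec = SimulationSpec(
        N=6, n=3, cohorts_per_setting=4,
        thresholds=(0.999999, 0.05, 0.001), seed=6,
    )
    cohorts = build_sim_cohorts(spec, model, ctrl, resp)
    return evaluate_tpr(cohorts, model, spec.thresholds, voxel_vol=0.25)


class TestEvaluateTPR:
    def test_threshold_near_one_flags_everything(self, table):
        loose = table[table.threshold == 0.999999]
        assert (loose.tpr == 1.0).all()
        assert (loose.fpr == 1.0).all()

    def test_tpr_monotone_in_threshold(self, table):
        for method, sub in table.groupby("method"):
            ordered = sub.sort_values("threshold", ascending=False)
            tprs = ordered.tpr.to_numpy()
            assert np.all(np.diff(tprs) <= 1e-12)

    def test_all_methods_reported(self, table):
        assert set(table.method) == {
            "lpm_tumor", "lpm_cohort", "t_volume", "t_mean", "t_p95"
        }

    def test_fpr_flagged_nan_without_null_cohorts(self, pools):
        model, ctrl, resp = pools
        spec = SimulationSpec(N=4, n=4, cohorts_per_setting=2, seed=7)
        cohorts = build_sim_cohorts(spec, model, ctrl, resp, include_null=False)
        table = evaluate_tpr(cohorts, model, (0.05,))
        coh = table[table.method == "lpm_cohort"]
        assert np.isnan(coh.fpr).all()

    def test_null_per_tumor_fpr_calibrated(self, truth_component_model):
        # against the known-component model, null tumors' one-sided p is
        # conservative: FPR at threshold alpha stays at or below ~alpha
        model = truth_component_model
        cfg = L.TruthConfig(n_control=0, n_treated=0)
        rng = np.random.default_rng(8)
        w = np.array([900.0, 1100.0, 0.0])
        ps = []
        for _ in range(1000):
            counts = rng.poisson(model.P @ w).reshape(
                (model.grid.n_bins, model.grid.n_visits), order="F"
            )
            h = L.TumorHistogram("n", "control", counts, model.grid)
            ps.append(model.fit_tumor(h).assess().p_value)
        ps = np.asarray(ps)
        for alpha in (0.05, 0.01):
            fpr = (ps < alpha).mean()
            # binomial error band around alpha at 1000 tumors
            assert fpr <= alpha + 3 * np.sqrt(alpha * (1 - alpha) / 1000)
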