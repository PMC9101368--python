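"""Shared fixtures: small synthetic studies and trained models.

Session-scoped so the EM trainings run once; all randomness is seeded.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import lpmadc as L


@pytest.fixture(scope="session")
def small_config() -> L.TruthConfig:
    """A reduced study (fewer tumors/bins/voxels) for fast unit tests."""
    return L.TruthConfig(
        n_control=8, n_treated=6, n_bins=60, voxels_per_tumor=1200, seed=5
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    hists, truth, tm = L.generate_study(small_config, seed=5)
    return hists, truth, tm


@pytest.fixture(scope="session")
def small_models(small_study):
    hists, truth, _ = small_study
    ctrl = [h for h in hists if h.cohort == "control"]
    trt = [h for h in hists if h.cohort == "treated"]
    cfg = L.LPMConfig(k_range=(1, 2, 3), restarts=6)
    control = L.LinearPoissonModel(ctrl, cfg).fit(seed=2)
    full = control.extend(trt, seed=2)
    return control, full


@pytest.fixture(scope="session")
def default_study():
    """The default study conditions: 15 control + 9 treated tumors,
    2000 voxels each, two visits, all treated responding with 30-70%
    of tissue affected."""
    cfg = L.TruthConfig()
    hists, truth, tm = L.generate_study(cfg, seed=11)
    return cfg, hists, truth, tm


@pytest.fixture(scope="session")
def default_models(default_study):
    _, hists, _, _ = default_study
    ctrl = [h for h in hists if h.cohort == "control"]
    trt = [h for h in hists if h.cohort == "treated"]
    cfg = L.LPMConfig(k_range=(1, 2, 3, 4), restarts=8)
    control = L.LinearPoissonModel(ctrl, cfg).fit(seed=3)
    full = control.extend(trt, seed=3)
    return control, full


@pytest.fixture(scope="session")
def truth_component_model(default_study):
    """An LPMResults built directly from the generator's true PMFs —
    the known-component reference model for calibration checks."""
    _, _, _, tm = default_study
    comps = [
        L.PMFComponent(tm.control_pmfs[:, i], "control")
        for i in range(tm.control_pmfs.shape[1])
    ] + [L.PMFComponent(tm.treatment_pmf, "treatment")]
    return L.LPMResults(
        grid=tm.grid,
        components=comps,
        training_weights=pd.DataFrame(),
        loglik=0.0,
        loglik_history=np.asarray([]),
        selection_reports={},
        sufficient=True,
        seed=0,
        config=L.LPMConfig(),
        training_ids=[],
    )
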