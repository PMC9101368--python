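"""Monte Carlo cohort simulation: TPR/FPR of LPM vs t-test readouts.

Simulated tumors are synthesised from a trained model: a random pair of
fitted base tumors is selected, their mixing weights are interpolated
(uniformly on the interval between the pair's values) and then perturbed
by a bounded random factor so that no weight deviates by more than the
configured fraction (default half) of its original value; bin counts are
then drawn Poisson around the mixed expectation.  Treatment cohorts mix
``n`` responder-derived and ``N - n`` control-derived tumors; control
(null) cohorts use control pairs only.  Each generated treatment or null
cohort carries a paired control cohort of equal size so the conventional
cohort t-tests have a comparator.

Detection methods evaluated per p-value threshold:

- ``lpm_tumor``   — per-tumor one-sided p from Z = QT/sigma;
- ``lpm_cohort``  — cohort-combined Z = sum QT / sqrt(sum sigma^2);
- ``t_volume`` / ``t_mean`` / ``t_p95`` — Welch t-tests of the
  visit-to-visit change in the conventional summary parameter between
  the cohort and its paired control cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .histogram import TumorHistogram
from .inference import cohort_t_test, summary_params
from .model import LPMResults, TumorFitResults

__all__ = [
    "SimulationSpec",
    "SimTumor",
    "SimCohort",
    "synthesize_histogram",
    "build_sim_cohorts",
    "evaluate_tpr",
]


@dataclass
class SimulationSpec:
    """One simulation setting."""

    N: int                                   #: cohort size
    n: int                                   #: responding subset size
    cohorts_per_setting: int = 10
    thresholds: tuple[float, ...] = (0.05, 0.01, 0.001)
    deviation_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.n <= self.N):
            raise ValueError("need 0 <= n <= N")
        if not all(0.0 < t < 1.0 for t in self.thresholds):
            raise ValueError("thresholds must lie in (0, 1)")
        if not (0.0 <= self.deviation_fraction <= 0.5):
            raise ValueError("deviation_fraction must be in [0, 0.5]")


@dataclass
class SimTumor:
    histogram: TumorHistogram
    responder: bool            #: truth label (derived from responder pair)
    weights: np.ndarray        #: mixing weights used for synthesis


@dataclass
class SimCohort:
    tumors: list[SimTumor]
    control_reference: list[SimTumor]   #: paired control cohort (same size)
    is_null: bool                       #: True when built from controls only

    @property
    def n_responders(self) -> int:
        return sum(t.responder for t in self.tumors)


def _mix_weights(
    wa: np.ndarray, wb: np.ndarray, deviation: float, rng: np.random.Generator
) -> np.ndarray:
    u = rng.uniform(size=wa.shape)
    w = u * wa + (1.0 - u) * wb
    w = w * rng.uniform(1.0 - deviation, 1.0 + deviation, size=w.shape)
    return np.maximum(w, 0.0)


def synthesize_histogram(
    model: LPMResults,
    fit_a: TumorFitResults | np.ndarray,
    fit_b: TumorFitResults | np.ndarray,
    deviation: float,
    rng: np.random.Generator,
    tumor_id: str = "sim",
    cohort: str = "simulated",
) -> tuple[TumorHistogram, np.ndarray]:
    """Synthesise one histogram from a pair of fitted base tumors.

    Returns ``(histogram, mixing_weights)``.  Both fits must be against
    the same model; ``deviation`` must not exceed 0.5 so realised weights
    stay within +/-50% of the enclosing pair interval.
    """
    if deviation > 0.5 or deviation < 0.0:
        raise ValueError("deviation must be in [0, 0.5]")
    wa = fit_a.weights if isinstance(fit_a, TumorFitResults) else np.asarray(fit_a)
    wb = fit_b.weights if isinstance(fit_b, TumorFitResults) else np.asarray(fit_b)
    for fit in (fit_a, fit_b):
        if isinstance(fit, TumorFitResults) and fit.model is not model:
            if fit.model.grid != model.grid or fit.model.n_components != model.n_components:
                raise ValueError("pair fits come from a different model")
    if wa.shape != (model.n_components,) or wb.shape != (model.n_components,):
        raise ValueError("weight vectors do not match the model components")
    w = _mix_weights(wa, wb, deviation, rng)
    expectation = model.P @ w
    counts = rng.poisson(expectation).reshape(
        (model.grid.n_bins, model.grid.n_visits), order="F"
    )
    if counts.sum() == 0:
        counts[0, 0] = 1
    return TumorHistogram(tumor_id, cohort, counts, model.grid), w


def build_sim_cohorts(
    spec: SimulationSpec,
    model: LPMResults,
    control_fits: Sequence[TumorFitResults | np.ndarray],
    responder_fits: Sequence[TumorFitResults | np.ndarray],
    include_null: bool = True,
    rng: np.random.Generator | None = None,
) -> list[SimCohort]:
    """Generate labelled treatment (and optional null) cohorts.

    Each treatment cohort holds exactly ``spec.n`` responder-derived and
    ``spec.N - spec.n`` control-derived tumors.  Null cohorts (and every
    paired control reference) are built from control pairs only.
    """
    if not control_fits:
        raise ValueError("control fit pool is empty")
    if spec.n > 0 and not responder_fits:
        raise ValueError("responder fit pool is empty but n > 0")
    rng = rng or np.random.default_rng(spec.seed)

    def _draw(pool, responder: bool, idx: int) -> SimTumor:
        i, j = rng.integers(0, len(pool), size=2)
        hist, w = synthesize_histogram(
            model, pool[i], pool[j], spec.deviation_fraction, rng,
            tumor_id=f"sim{idx:04d}",
            cohort="responder" if responder else "control",
        )
        return SimTumor(hist, responder, w)

    cohorts: list[SimCohort] = []
    counter = 0
    for _ in range(spec.cohorts_per_setting):
        tumors = [_draw(responder_fits, True, counter + i) for i in range(spec.n)]
        tumors += [
            _draw(control_fits, False, counter + spec.n + i)
            for i in range(spec.N - spec.n)
        ]
        reference = [
            _draw(control_fits, False, counter + spec.N + i) for i in range(spec.N)
        ]
        counter += 2 * spec.N
        cohorts.append(SimCohort(tumors, reference, is_null=False))
        if include_null:
            null = [_draw(control_fits, False, counter + i) for i in range(spec.N)]
            null_ref = [
                _draw(control_fits, False, counter + spec.N + i)
                for i in range(spec.N)
            ]
            counter += 2 * spec.N
            cohorts.append(SimCohort(null, null_ref, is_null=True))
    return cohorts


def _summary_changes(
    tumors: Sequence[SimTumor], model: LPMResults, voxel_vol: float
) -> pd.DataFrame:
    """Per-tumor visit-to-visit change in volume, mean ADC and p95 ADC."""
    grid = model.grid
    rows = []
    for t in tumors:
        first = t.histogram.counts[:, 0]
        last = t.histogram.counts[:, -1]
        sp_first = summary_params(first, grid.adc_edges, voxel_vol)
        sp_last = summary_params(last, grid.adc_edges, voxel_vol)
        rows.append(
            {
                "volume": sp_last.volume - sp_first.volume,
                "mean": sp_last.mean_adc - sp_first.mean_adc,
                "p95": sp_last.p95_adc - sp_first.p95_adc,
            }
        )
    return pd.DataFrame(rows)


def evaluate_tpr(
    cohorts: Sequence[SimCohort],
    model: LPMResults,
    thresholds: Sequence[float] = (0.05, 0.01, 0.001),
    voxel_vol: float = 0.25,
) -> pd.DataFrame:
    """Score every detection method at every threshold.

    Returns a tidy frame with columns ``method``, ``threshold``, ``tpr``,
    ``fpr``, ``n_true``, ``n_null``.  Per-tumor rates count individual
    tumors; cohort-level rates count cohorts.  FPR columns are NaN when no
    null cohorts/tumors are present (flagged, not silently zero).
    """
    per_tumor_p_true: list[float] = []
    per_tumor_p_null: list[float] = []
    cohort_rows = []

    for c in cohorts:
        fits = [model.fit_tumor(t.histogram) for t in c.tumors]
        assessments = [f.assess() for f in fits]
        for t, a in zip(c.tumors, assessments):
            if t.responder:
                per_tumor_p_true.append(a.p_value)
            else:
                per_tumor_p_null.append(a.p_value)
        qt = np.array([a.QT for a in assessments])
        var = np.array([a.sigma_QT**2 for a in assessments])
        z_cohort = qt.sum() / np.sqrt(var.sum()) if var.sum() > 0 else 0.0
        p_cohort = float(stats.norm.sf(z_cohort))

        changes_t = _summary_changes(c.tumors, model, voxel_vol)
        changes_c = _summary_changes(c.control_reference, model, voxel_vol)
        p_tests = {}
        for param in ("volume", "mean", "p95"):
            try:
                p_tests[param] = cohort_t_test(
                    changes_c[param], changes_t[param]
                )
            except ValueError:
                p_tests[param] = 1.0
        cohort_rows.append(
            {"is_null": c.is_null, "p_lpm_cohort": p_cohort, **{
                f"p_t_{k}": v for k, v in p_tests.items()}}
        )

    cdf = pd.DataFrame(cohort_rows)
    true_cohorts = cdf[~cdf["is_null"]]
    null_cohorts = cdf[cdf["is_null"]]
    p_true = np.asarray(per_tumor_p_true)
    p_null = np.asarray(per_tumor_p_null)

    rows = []
    for thr in thresholds:
        rows.append(
            {
                "method": "lpm_tumor",
                "threshold": thr,
                "tpr": float((p_true < thr).mean()) if p_true.size else np.nan,
                "fpr": float((p_null < thr).mean()) if p_null.size else np.nan,
                "n_true": p_true.size,
                "n_null": p_null.size,
            }
        )
        rows.append(
            {
                "method": "lpm_cohort",
                "threshold": thr,
                "tpr": float((true_cohorts["p_lpm_cohort"] < thr).mean())
                if len(true_cohorts)
                else np.nan,
                "fpr": float((null_cohorts["p_lpm_cohort"] < thr).mean())
                if len(null_cohorts)
                else np.nan,
                "n_true": len(true_cohorts),
                "n_null": len(null_cohorts),
            }
        )
        for param in ("volume", "mean", "p95"):
            col = f"p_t_{param}"
            rows.append(
                {
                    "method": f"t_{param}",
                    "threshold": thr,
                    "tpr": float((true_cohorts[col] < thr).mean())
                    if len(true_cohorts)
                    else np.nan,
                    "fpr": float((null_cohorts[col] < thr).mean())
                    if len(null_cohorts)
                    else np.nan,
                    "n_true": len(true_cohorts),
                    "n_null": len(null_cohorts),
                }
            )
    return pd.DataFrame(rows)
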