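"""Per-tumor response readouts from a fitted Linear Poisson Model.

The treatment-attributed voxel count ``QT = sum_t Q_t`` is a lower bound
on the volume affected by therapy.  Its standard error comes from the
weight covariance (observed Fisher information of the extended Poisson
likelihood, PMFs fixed), giving a Z score ``QT / sigma_QT`` — standard
deviations of change away from zero — and a one-sided normal p-value.
Bayes' theorem over the fitted class expectations yields per-(bin, visit)
classification posteriors, and the model expectation decomposes into
treatment-affected and unaffected sub-distributions from which the
conventional summary parameters (mean ADC, 95th percentile, volume) are
computed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .model import LPMResults, TumorFitResults

__all__ = [
    "ResponseAssessment",
    "SummaryParams",
    "posterior_maps",
    "assess_response",
    "decompose_distribution",
    "summary_params",
    "cohort_t_test",
]


@dataclass
class ResponseAssessment:
    """QT +/- sigma, Z score and the decomposed sub-distributions."""

    tumor_id: str
    QT: float
    QC: float
    sigma_QT: float
    z: float
    p_value: float
    responder: bool
    z_threshold: float
    affected_hist: np.ndarray      #: (n_bins, n_visits) treatment expectation
    unaffected_hist: np.ndarray    #: (n_bins, n_visits) control expectation


@dataclass
class SummaryParams:
    """Conventional whole- or sub-distribution summary parameters."""

    mean_adc: float    #: mm^2/s
    p95_adc: float     #: mm^2/s
    volume: float      #: mm^3


def posterior_maps(
    model: LPMResults, fit: TumorFitResults
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-cell class posteriors P(C=t|A,V), P(C=c|A,V) via Bayes' theorem.

    Returns ``(post_t, post_c, supported)`` flat arrays; cells with zero
    model mass are undefined (NaN) and flagged False in ``supported``.
    """
    P = model.P
    m_t = P[:, model.is_treatment] @ fit.weights[model.is_treatment]
    m_c = P[:, ~model.is_treatment] @ fit.weights[~model.is_treatment]
    m = m_t + m_c
    supported = m > 0
    post_t = np.full(m.shape, np.nan)
    post_c = np.full(m.shape, np.nan)
    post_t[supported] = m_t[supported] / m[supported]
    post_c[supported] = m_c[supported] / m[supported]
    return post_t, post_c, supported


def decompose_distribution(
    model: LPMResults, fit: TumorFitResults
) -> tuple[np.ndarray, np.ndarray]:
    """Split the fitted expectation into (affected, unaffected) parts.

    ``affected = sum_t P(A,V|t) Q_t`` and symmetrically for control; the
    two sum bin-wise to the fitted expectation, and integrate to QT and
    QC respectively.  Shapes are (n_bins, n_visits).
    """
    P = model.P
    shape = (model.grid.n_bins, model.grid.n_visits)
    affected = (P[:, model.is_treatment] @ fit.weights[model.is_treatment]).reshape(
        shape, order="F"
    )
    unaffected = (P[:, ~model.is_treatment] @ fit.weights[~model.is_treatment]).reshape(
        shape, order="F"
    )
    return affected, unaffected


def assess_response(
    model: LPMResults, fit: TumorFitResults, z_threshold: float = 3.0
) -> ResponseAssessment:
    """Compute QT +/- sigma, Z, p and the responder call for one tumor.

    sigma_QT aggregates the treatment block of the weight covariance
    (sum of rows/columns); Z is defined as 0 whenever QT is 0.
    """
    t_mask = model.is_treatment
    QT = float(fit.weights[t_mask].sum())
    QC = float(fit.weights[~t_mask].sum())
    var = float(fit.weight_covariance[np.ix_(t_mask, t_mask)].sum())
    sigma = float(np.sqrt(max(var, 0.0)))
    z = QT / sigma if (QT > 0 and sigma > 0) else 0.0
    p = float(stats.norm.sf(z))
    affected, unaffected = decompose_distribution(model, fit)
    return ResponseAssessment(
        tumor_id=fit.histogram.tumor_id,
        QT=QT,
        QC=QC,
        sigma_QT=sigma,
        z=z,
        p_value=p,
        responder=bool(z > z_threshold),
        z_threshold=z_threshold,
        affected_hist=affected,
        unaffected_hist=unaffected,
    )


def summary_params(
    hist: np.ndarray, adc_edges: np.ndarray, voxel_vol: float
) -> SummaryParams:
    """Mean ADC, 95th percentile and volume of one per-visit distribution.

    ``hist`` is a nonnegative (possibly real-valued) distribution over the
    ADC bins of a single visit.  The mean is the count-weighted bin-center
    mean; the 95th percentile is the smallest bin center whose cumulative
    mass fraction reaches 0.95; the volume is total mass times the voxel
    volume.
    """
    hist = np.asarray(hist, dtype=float).ravel()
    edges = np.asarray(adc_edges, dtype=float)
    if hist.size != edges.size - 1:
        raise ValueError("histogram length does not match the bin edges")
    if np.any(hist < 0):
        raise ValueError("distribution must be nonnegative")
    total = hist.sum()
    if total <= 0:
        raise ValueError("distribution has zero total mass")
    centers = 0.5 * (edges[:-1] + edges[1:])
    mean = float(np.sum(centers * hist) / total)
    cum = np.cumsum(hist) / total
    p95 = float(centers[np.searchsorted(cum, 0.95)])
    return SummaryParams(mean_adc=mean, p95_adc=p95, volume=float(total * voxel_vol))


def cohort_t_test(control_values, treated_values) -> float:
    """Two-sample Welch t-test (two-sided p) between cohort parameter lists."""
    a = np.asarray(control_values, dtype=float)
    b = np.asarray(treated_values, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    if np.var(a) == 0 and np.var(b) == 0:
        raise ValueError("zero variance in both groups: t-test undefined")
    return float(stats.ttest_ind(a, b, equal_var=False).pvalue)
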