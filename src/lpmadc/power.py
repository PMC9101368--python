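"""Power calculations for study design.

Two questions are answered before an experiment is run:

1. How many independent voxels must a tumor contribute for the
   treatment-attributed volume to reach a target Z score?  The attainable
   Z grows with the square root of the total voxel count ``Qtotal = QT + QC``
   and is penalised by the *ambiguity* between control and treated
   distributions, summarised by the terms ``T*`` and ``C*`` (mass-weighted
   mean class posteriors; both 1 for perfectly separated distributions,
   0.5 for indistinguishable ones):

       Z = sqrt( Qtotal * ( T* - (1 - T* - C*)^2 / (4 C*) ) )

2. If only a fraction ``F`` of tumors respond biologically, how large a
   cohort ``N`` is needed to observe at least one responder?  Binomial
   theory gives

       P_detect = sum_{r=1..N} C(N, r) F^r (1-F)^(N-r)  =  1 - (1-F)^N

   (the closed form is an identity; the sum is what is implemented).
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

import numpy as np

from .model import LPMResults, TumorFitResults

__all__ = [
    "AmbiguityTerms",
    "ambiguity_terms",
    "predict_z",
    "detection_probability",
    "min_cohort_for_confidence",
]


@dataclass(frozen=True)
class AmbiguityTerms:
    """Overlap summary between control and treated distributions.

    ``T_star`` is the mean treatment posterior over treatment-attributed
    model mass; ``C_star`` the mean control posterior over
    control-attributed mass.  Both lie in (0, 1]: 1 means the class is
    perfectly identifiable from the data distribution, 0.5 means complete
    ambiguity.
    """

    T_star: float
    C_star: float

    def __post_init__(self) -> None:
        for name, v in (("T_star", self.T_star), ("C_star", self.C_star)):
            if not (0.0 < v <= 1.0 + 1e-12):
                raise ValueError(f"{name} must be in (0, 1], got {v}")


def ambiguity_terms(
    model: LPMResults, reference_fits: list[TumorFitResults]
) -> AmbiguityTerms:
    """Estimate T* and C* from fitted reference tumors.

    The class posteriors are averaged over the corresponding class's
    fitted expectation, pooled across the reference fits (typically
    similar past experiments):
    ``T* = sum m_t P(C=t) / sum m_t`` with ``m_t`` the treatment-attributed
    expectation per cell, and symmetrically for ``C*``.
    """
    if not any(model.is_treatment):
        raise ValueError("model has no treatment components")
    if not reference_fits:
        raise ValueError("at least one reference fit is required")
    P = model.P
    t_num = t_den = c_num = c_den = 0.0
    for fit in reference_fits:
        m_t = P[:, model.is_treatment] @ fit.weights[model.is_treatment]
        m_c = P[:, ~model.is_treatment] @ fit.weights[~model.is_treatment]
        m = m_t + m_c
        sup = m > 0
        post_t = np.zeros_like(m)
        post_t[sup] = m_t[sup] / m[sup]
        t_num += float((m_t * post_t).sum())
        t_den += float(m_t.sum())
        c_num += float((m_c * (1.0 - post_t))[sup].sum())
        c_den += float(m_c.sum())
    if t_den <= 0 or c_den <= 0:
        raise ValueError("reference fits carry no mass for one of the classes")
    return AmbiguityTerms(T_star=t_num / t_den, C_star=c_num / c_den)


def predict_z(Q_total: float, amb: AmbiguityTerms) -> float:
    """Predicted attainable Z score for a tumor with ``Q_total`` voxels.

    Implements ``Z = sqrt(Qtotal (T* - (1-T*-C*)^2 / (4 C*)))``; the
    bracket can go negative for extreme ambiguity, in which case the
    prediction is clipped at 0.  Doubling of Z under quadrupling of
    ``Q_total`` is exact.
    """
    if Q_total < 0:
        raise ValueError("Q_total must be nonnegative")
    if amb.C_star <= 0:
        raise ValueError("C_star must be positive")
    bracket = amb.T_star - (1.0 - amb.T_star - amb.C_star) ** 2 / (4.0 * amb.C_star)
    return float(np.sqrt(Q_total * max(bracket, 0.0)))


def detection_probability(N: int, F: float) -> float:
    """Probability of observing at least one responder in a cohort of N.

    Evaluated as the binomial sum over r = 1..N responders; equals
    ``1 - (1-F)^N``.
    """
    if N < 1 or int(N) != N:
        raise ValueError("N must be a positive integer")
    if not (0.0 <= F <= 1.0):
        raise ValueError("F must be in [0, 1]")
    N = int(N)
    return float(
        sum(comb(N, r) * F**r * (1.0 - F) ** (N - r) for r in range(1, N + 1))
    )


def min_cohort_for_confidence(F: float, target: float, n_max: int = 10_000) -> int:
    """Smallest cohort size whose detection probability reaches ``target``."""
    if not (0.0 < F <= 1.0):
        raise ValueError("F must be in (0, 1] (F=0 can never reach a target)")
    if not (0.0 < target < 1.0):
        raise ValueError("target must be in (0, 1)")
    for n in range(1, n_max + 1):
        if detection_probability(n, F) >= target:
            return n
    raise ValueError(f"target {target} not reachable within N <= {n_max}")
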