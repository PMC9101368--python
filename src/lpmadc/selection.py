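"""Model sufficiency: chi-square per degree of freedom, Bland-Altman
residual checks, and leave-one-out (LOO) model-order selection.

A model is deemed sufficient when it has a low fit value
(sqrt of chi^2 per d.f.), produces no LOO outliers, and leaves
Poisson-consistent residuals.  Thresholds are configurable; defaults are
a median LOO fit value of 1.2 and an outlier rule of mean + 3 SD.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .em import em_fit, fit_weights

__all__ = [
    "pool_bins",
    "chi2_per_df",
    "bland_altman_check",
    "BlandAltmanResult",
    "SufficiencyReport",
    "loo_fit_values",
    "loo_select",
]

#: minimum expected count per chi^2 cell; lower-expectation bins are pooled
#: with neighbours so the Poisson chi^2 statistic stays calibrated
CHI2_FLOOR = 5.0


def pool_bins(
    observed: np.ndarray,
    expected: np.ndarray,
    floor: float = CHI2_FLOOR,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Pool adjacent bins until every pooled cell has expectation >= floor.

    Operates on 1-D arrays (callers pass one visit at a time or the
    flattened grid).  A trailing group that cannot reach the floor is
    merged into the previous group.  Returns (pooled_obs, pooled_exp,
    pooled_flag); the flag marks that any pooling happened.
    """
    observed = np.asarray(observed, dtype=float).ravel()
    expected = np.asarray(expected, dtype=float).ravel()
    if observed.shape != expected.shape:
        raise ValueError("observed and expected must have the same shape")
    obs_groups: list[float] = []
    exp_groups: list[float] = []
    acc_o = acc_e = 0.0
    for o, e in zip(observed, expected):
        if o == 0 and e == 0:
            continue
        acc_o += o
        acc_e += e
        if acc_e >= floor:
            obs_groups.append(acc_o)
            exp_groups.append(acc_e)
            acc_o = acc_e = 0.0
    if acc_e > 0 or acc_o > 0:
        if exp_groups:
            obs_groups[-1] += acc_o
            exp_groups[-1] += acc_e
        else:
            obs_groups.append(acc_o)
            exp_groups.append(acc_e)
    pooled = len(obs_groups) != int(np.sum((observed != 0) | (expected != 0)))
    return np.asarray(obs_groups), np.asarray(exp_groups), pooled


def chi2_per_df(
    observed: np.ndarray,
    expected: np.ndarray,
    n_params: int,
    floor: float = CHI2_FLOOR,
) -> float:
    """Pearson chi^2 per degree of freedom with low-count pooling.

    d.f. = (number of pooled cells) - n_params; nonpositive d.f. raises.
    """
    obs, exp, _ = pool_bins(observed, expected, floor)
    df = obs.size - n_params
    if df <= 0:
        raise ValueError(
            f"nonpositive degrees of freedom ({obs.size} cells, {n_params} params)"
        )
    if np.any(exp <= 0):
        raise ValueError("pooled expectation nonpositive; model lacks support")
    chi2 = float(np.sum((obs - exp) ** 2 / exp))
    return chi2 / df


@dataclass
class BlandAltmanResult:
    """Standardised-residual agreement check against expectation magnitude.

    Residuals r = (obs - exp) / sqrt(exp) on pooled cells should be ~unit
    Poisson noise: pass requires |mean r| < ``mean_tol`` overall and the
    residual SD within ``sd_range`` in every expectation-magnitude quintile
    (quintiles with < 3 cells are not scored).
    """

    passed: bool
    mean_residual: float
    sd_by_quintile: np.ndarray
    n_cells: int


def bland_altman_check(
    observed: np.ndarray,
    expected: np.ndarray,
    floor: float = CHI2_FLOOR,
    mean_tol: float = 0.1,
    sd_range: tuple[float, float] = (0.8, 1.2),
) -> BlandAltmanResult:
    obs, exp, _ = pool_bins(observed, expected, floor)
    r = (obs - exp) / np.sqrt(exp)
    order = np.argsort(exp)
    sds = []
    for chunk in np.array_split(order, 5):
        if chunk.size >= 3:
            sds.append(float(np.std(r[chunk], ddof=1)))
    sds_arr = np.asarray(sds)
    mean_r = float(r.mean())
    passed = abs(mean_r) < mean_tol and bool(
        np.all((sds_arr >= sd_range[0]) & (sds_arr <= sd_range[1]))
    )
    return BlandAltmanResult(passed, mean_r, sds_arr, r.size)


@dataclass
class SufficiencyReport:
    """Sufficiency evidence for one trained model order."""

    k: int
    fit_value: float                      #: sqrt(chi^2/d.f.) on training data
    loo_fits: dict[str, float] = field(default_factory=dict)
    loo_outliers: dict[str, bool] = field(default_factory=dict)
    bland_altman: BlandAltmanResult | None = None
    sufficient: bool = False
    threshold: float = 1.2

    @property
    def median_loo_fit(self) -> float:
        return float(np.median(list(self.loo_fits.values())))

    @property
    def has_outliers(self) -> bool:
        return any(self.loo_outliers.values())


def _outlier_flags(values: np.ndarray) -> np.ndarray:
    """Flag held-out fits above mean + 3 SD of the LOO fit distribution."""
    if values.size < 3:
        return np.zeros(values.size, dtype=bool)
    return values > values.mean() + 3.0 * values.std(ddof=1)


def loo_fit_values(
    H: np.ndarray,
    k_free: int,
    rng_seq: list[np.random.Generator],
    restarts: int,
    fixed_P: np.ndarray | None = None,
    floor: float = CHI2_FLOOR,
    max_iter: int = 2000,
    tol: float = 1e-8,
    support_builder=None,
) -> np.ndarray:
    """Held-out fit values sqrt(chi^2/d.f.) for each left-out tumor.

    For each column j of ``H`` the model is trained on the remaining
    columns and the held-out tumor is scored by a weights-only refit.
    ``rng_seq`` supplies one Generator per held-out tumor so results are
    reproducible and independent of evaluation order.
    ``support_builder(H_train, rng)``, when given, derives the cell
    support for the free components from each fold's training data.
    """
    n = H.shape[1]
    out = np.empty(n)
    K_tot = k_free + (0 if fixed_P is None else fixed_P.shape[1])
    for j in range(n):
        mask = np.ones(n, dtype=bool)
        mask[j] = False
        support = None
        k_fold = k_free
        if support_builder is not None and k_free > 0:
            support = support_builder(H[:, mask], rng_seq[j])
            if support is not None and support.sum() < k_free:
                k_fold = 0  # no demonstrable excess: degenerate to frozen-only
                support = None
        if k_fold == 0 and fixed_P is not None:
            P = fixed_P
        else:
            res = em_fit(
                H[:, mask], k_fold, rng_seq[j], restarts=restarts,
                fixed_P=fixed_P, max_iter=max_iter, tol=tol, support=support,
            )
            P = res.P
        q, _, _ = fit_weights(P, H[:, j])
        out[j] = np.sqrt(chi2_per_df(H[:, j], P @ q, K_tot, floor))
    return out


def loo_select(
    H: np.ndarray,
    k_range,
    seed: int,
    restarts: int = 20,
    fixed_P: np.ndarray | None = None,
    threshold: float = 1.2,
    floor: float = CHI2_FLOOR,
    max_iter: int = 2000,
    tol: float = 1e-8,
    tumor_ids: list[str] | None = None,
    support_builder=None,
) -> tuple[int, dict[int, SufficiencyReport], bool]:
    """Choose the model order by leave-one-out generalisation.

    Returns ``(selected_k, reports_by_k, sufficient)``.  The selected K is
    the smallest whose median held-out fit value is below ``threshold``
    with no LOO outliers; when no K qualifies, the K with the lowest
    median is returned with ``sufficient=False``.
    """
    k_range = list(k_range)
    if not k_range:
        raise ValueError("k_range must be nonempty")
    n = H.shape[1]
    if n < 3:
        raise ValueError("LOO selection needs at least 3 tumors")
    ids = tumor_ids or [str(j) for j in range(n)]
    root = np.random.SeedSequence(seed)
    reports: dict[int, SufficiencyReport] = {}
    selected: int | None = None
    for k in k_range:
        child = root.spawn(1)[0]
        rng_seq = [np.random.Generator(np.random.PCG64(s)) for s in child.spawn(n)]
        K_tot = k + (0 if fixed_P is None else fixed_P.shape[1])
        if K_tot < 1:
            continue
        fits = loo_fit_values(
            H, k, rng_seq, restarts, fixed_P, floor, max_iter, tol,
            support_builder=support_builder,
        )
        flags = _outlier_flags(fits)
        rep = SufficiencyReport(
            k=k,
            fit_value=float(np.median(fits)),
            loo_fits=dict(zip(ids, fits.tolist())),
            loo_outliers=dict(zip(ids, flags.tolist())),
            threshold=threshold,
        )
        rep.sufficient = rep.median_loo_fit <= threshold and not rep.has_outliers
        reports[k] = rep
        if rep.sufficient and selected is None:
            selected = k
            break
    if selected is not None:
        return selected, reports, True
    best = min(reports, key=lambda k: reports[k].median_loo_fit)
    return best, reports, False
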