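"""Linear Poisson Modelling of multi-visit ADC histograms.

The model describes each tumor histogram ``H(A, V)`` as a nonnegative
mixture of shared probability-mass-function components with Poisson bin
noise:

    H(A, V)  ~=  M(A, V | C=c) + M(A, V | C=t)
    M(A, V | C=k) = sum_k P(A, V | C=k) Q_k

Components are trained in two stages: the *control* part is learned from
control-cohort tumors only; *treatment* components are then added with
the control PMFs frozen, so they only capture behaviour absent from the
control model.  Per-tumor component weights ``Q`` are always free.

Usage follows the model/results convention::

    model = LinearPoissonModel(control_histograms)
    control = model.fit(seed=0)                # LOO-selected order
    full = control.extend(treated_histograms)  # adds treatment components
    fit = full.fit_tumor(histogram)            # weights-only refit
    assessment = fit.assess()                  # QT +/- sigma, Z, p
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from . import em as _em
from . import selection as _sel
from .histogram import BinGrid, TumorHistogram

__all__ = ["PMFComponent", "LPMConfig", "LinearPoissonModel", "LPMResults",
           "TumorFitResults"]

CONTROL = "control"
TREATMENT = "treatment"


@dataclass(frozen=True)
class PMFComponent:
    """One generative habitat: a PMF over the (bin, visit) grid plus its
    class label (control-behaviour or additional treatment behaviour)."""

    probs: np.ndarray          #: flat (n_cells,) PMF, visit-major order
    class_label: str

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float).ravel()
        if np.any(p < 0):
            raise ValueError("component probabilities must be nonnegative")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("component PMF must sum to 1 within 1e-9")
        if self.class_label not in (CONTROL, TREATMENT):
            raise ValueError(f"unknown class label {self.class_label!r}")
        object.__setattr__(self, "probs", p)


@dataclass
class LPMConfig:
    """Training configuration.

    k_range / k_range_treatment bound the LOO model-order search for the
    two stages (treatment search starts at 0: a treated cohort that the
    control model already explains needs no extra components).  The EM
    stops on a relative log-likelihood change below ``tol`` or at
    ``max_iter``; ``restarts`` random restarts guard against local
    maxima.  ``sufficiency_threshold`` is the maximum acceptable median
    LOO fit value sqrt(chi^2/d.f.); ``merge_cosine`` triggers post-fit
    merging of near-duplicate (degenerate) components.
    """

    k_range: Sequence[int] = tuple(range(1, 7))
    k_range_treatment: Sequence[int] = tuple(range(0, 4))
    restarts: int = 20
    max_iter: int = 2000
    tol: float = 1e-8
    sufficiency_threshold: float = 1.2
    chi2_floor: float = _sel.CHI2_FLOOR
    merge_cosine: float = 0.999
    #: Treatment components are restricted to grid cells where the treated
    #: cohort shows a pooled standardised excess above this z over the
    #: control fit (two passes: against a control-only fit, then against
    #: the control part of a provisional full fit).  Without the
    #: restriction the treatment shapes absorb diffuse Poisson noise from
    #: the whole grid and systematically inflate QT on unseen tumors.
    treatment_support_z: float = 2.0
    #: ADC-bin dilation widths applied to the two support passes (the
    #: second pass recovers low-excess mode shoulders, so needs less).
    treatment_support_dilation: tuple[int, int] = (2, 1)


def _as_matrix(histograms: Sequence[TumorHistogram]) -> np.ndarray:
    return np.column_stack([h.flat for h in histograms]).astype(float)


def _check_shared_grid(histograms: Sequence[TumorHistogram]) -> BinGrid:
    if not histograms:
        raise ValueError("no histograms supplied")
    grid = histograms[0].grid
    for h in histograms[1:]:
        if h.grid != grid:
            raise ValueError(f"tumor {h.tumor_id} is on a different grid")
    return grid


def _merge_degenerate(
    P: np.ndarray, Q: np.ndarray, n_frozen: int, cosine: float
) -> tuple[np.ndarray, np.ndarray]:
    """Merge near-parallel free components (linear models are commonly
    degenerate); frozen columns are never touched."""
    while True:
        K = P.shape[1]
        merged = False
        for a in range(n_frozen, K):
            for b in range(a + 1, K):
                na, nb = np.linalg.norm(P[:, a]), np.linalg.norm(P[:, b])
                if na == 0 or nb == 0:
                    continue
                if float(P[:, a] @ P[:, b] / (na * nb)) > cosine:
                    wa, wb = Q[a].sum(), Q[b].sum()
                    w = wa + wb
                    mix = (
                        (wa * P[:, a] + wb * P[:, b]) / w
                        if w > 0
                        else 0.5 * (P[:, a] + P[:, b])
                    )
                    Q[a] = Q[a] + Q[b]
                    P = np.delete(P, b, axis=1)
                    Q = np.delete(Q, b, axis=0)
                    P[:, a] = mix / mix.sum()
                    merged = True
                    break
            if merged:
                break
        if not merged:
            return P, Q


def _dilate_mask(mask: np.ndarray, n_bins: int, n_visits: int, width: int) -> np.ndarray:
    """Dilate a flat cell mask along the ADC-bin axis within each visit."""
    if width <= 0:
        return mask
    m = mask.reshape((n_bins, n_visits), order="F")
    out = m.copy()
    for d in range(1, width + 1):
        out[:-d, :] |= m[d:, :]
        out[d:, :] |= m[:-d, :]
    return out.reshape(-1, order="F")


def _treatment_support(
    H: np.ndarray,
    P_ctrl: np.ndarray,
    n_bins: int,
    n_visits: int,
    cfg: "LPMConfig",
    rng: np.random.Generator,
) -> np.ndarray:
    """Cells where the treated cohort shows significant excess over control.

    Pass 1 scores the pooled standardised residual of control-only
    weights fits (which over-attribute to control, so the threshold is
    dilated to recover shoulders); a provisional one-component treatment
    fit on that support then yields a cleaner control attribution, and
    pass 2 re-scores the excess of the data over the control *part* of
    the provisional fit.  The result bounds where treatment components
    may carry mass.
    """
    z_thr = cfg.treatment_support_z
    d1, d2 = cfg.treatment_support_dilation
    n_cells, n_tum = H.shape

    excess = np.zeros(n_cells)
    var = np.zeros(n_cells)
    for j in range(n_tum):
        q, _, _ = _em.fit_weights(P_ctrl, H[:, j], max_iter=cfg.max_iter)
        m = P_ctrl @ q
        excess += H[:, j] - m
        var += np.maximum(m, 1e-9)
    sup1 = _dilate_mask(excess / np.sqrt(var) > z_thr, n_bins, n_visits, d1)
    if sup1.sum() < 1:
        return sup1

    res = _em.em_fit(
        H, 1, rng, restarts=cfg.restarts, fixed_P=P_ctrl,
        max_iter=cfg.max_iter, tol=cfg.tol, support=sup1,
    )
    n_ctrl = P_ctrl.shape[1]
    excess = np.zeros(n_cells)
    var = np.zeros(n_cells)
    for j in range(n_tum):
        q, _, _ = _em.fit_weights(res.P, H[:, j], max_iter=cfg.max_iter)
        m_c = P_ctrl @ q[:n_ctrl]
        m = res.P @ q
        excess += H[:, j] - m_c
        var += np.maximum(m, 1e-9)
    return _dilate_mask(excess / np.sqrt(var) > z_thr, n_bins, n_visits, d2)


class LinearPoissonModel:
    """Two-part Linear Poisson Model builder.

    Parameters
    ----------
    histograms
        Control-cohort tumor histograms sharing one grid.
    config
        Optional :class:`LPMConfig`; defaults are conservative.
    """

    def __init__(
        self,
        histograms: Sequence[TumorHistogram],
        config: LPMConfig | None = None,
    ) -> None:
        self.grid = _check_shared_grid(histograms)
        self.histograms = list(histograms)
        self.config = config or LPMConfig()

    def fit(self, k: int | None = None, seed: int = 0) -> "LPMResults":
        """Train the control part.

        With ``k=None`` the component count is selected by leave-one-out
        generalisation over ``config.k_range``; otherwise ``k`` components
        are fitted directly (LOO sufficiency is still reported when at
        least three tumors are available).
        """
        cfg = self.config
        H = _as_matrix(self.histograms)
        ids = [h.tumor_id for h in self.histograms]
        root = np.random.SeedSequence(seed)
        sel_seed, fit_seed = [int(s.generate_state(1)[0] % (2**31)) for s in root.spawn(2)]

        reports: dict[int, _sel.SufficiencyReport] = {}
        sufficient = True
        if k is None:
            k, reports, sufficient = _sel.loo_select(
                H, cfg.k_range, sel_seed, cfg.restarts,
                threshold=cfg.sufficiency_threshold, floor=cfg.chi2_floor,
                max_iter=cfg.max_iter, tol=cfg.tol, tumor_ids=ids,
            )
        elif len(self.histograms) >= 3:
            _, reports, sufficient = _sel.loo_select(
                H, [k], sel_seed, cfg.restarts,
                threshold=cfg.sufficiency_threshold, floor=cfg.chi2_floor,
                max_iter=cfg.max_iter, tol=cfg.tol, tumor_ids=ids,
            )

        rng = np.random.Generator(np.random.PCG64(fit_seed))
        res = _em.em_fit(
            H, k, rng, restarts=cfg.restarts, max_iter=cfg.max_iter, tol=cfg.tol
        )
        P, Q = _merge_degenerate(res.P, res.Q, 0, cfg.merge_cosine)
        components = [PMFComponent(P[:, i].copy(), CONTROL) for i in range(P.shape[1])]
        return LPMResults(
            grid=self.grid,
            components=components,
            training_weights=pd.DataFrame(
                Q.T, index=ids, columns=_component_names(components)
            ),
            loglik=res.loglik,
            loglik_history=res.loglik_history,
            selection_reports=reports,
            sufficient=sufficient,
            seed=seed,
            config=cfg,
            training_ids=ids,
            control_histograms=self.histograms,
        )


def _component_names(components: Sequence[PMFComponent]) -> list[str]:
    names, nc, nt = [], 0, 0
    for c in components:
        if c.class_label == CONTROL:
            names.append(f"c{nc}")
            nc += 1
        else:
            names.append(f"t{nt}")
            nt += 1
    return names


@dataclass
class LPMResults:
    """A trained Linear Poisson Model plus its training diagnostics."""

    grid: BinGrid
    components: list[PMFComponent]
    training_weights: pd.DataFrame
    loglik: float
    loglik_history: np.ndarray
    selection_reports: dict[int, _sel.SufficiencyReport]
    sufficient: bool
    seed: int
    config: LPMConfig
    training_ids: list[str]
    control_histograms: list[TumorHistogram] = field(default_factory=list)

    # -- basic structure ----------------------------------------------------
    @property
    def P(self) -> np.ndarray:
        """(n_cells, K) matrix of component PMFs."""
        return np.column_stack([c.probs for c in self.components])

    @property
    def labels(self) -> np.ndarray:
        return np.asarray([c.class_label for c in self.components])

    @property
    def is_treatment(self) -> np.ndarray:
        return self.labels == TREATMENT

    @property
    def n_components(self) -> int:
        return len(self.components)

    @property
    def component_names(self) -> list[str]:
        return _component_names(self.components)

    @property
    def control_P(self) -> np.ndarray:
        return np.column_stack(
            [c.probs for c in self.components if c.class_label == CONTROL]
        )

    def selection_curves(self) -> pd.DataFrame:
        """Tidy frame of held-out fit values per candidate model order."""
        rows = []
        for k, rep in self.selection_reports.items():
            for tid, v in rep.loo_fits.items():
                rows.append((k, tid, v, rep.loo_outliers[tid]))
        return pd.DataFrame(rows, columns=["k", "tumor_id", "loo_fit", "outlier"])

    # -- second training stage ----------------------------------------------
    def extend(
        self,
        treated_histograms: Sequence[TumorHistogram],
        k: int | None = None,
        seed: int = 0,
    ) -> "LPMResults":
        """Add treatment components with the control PMFs frozen.

        Only new treatment-labelled component shapes and all weights are
        free; the control PMFs are carried over bit-for-bit.  The number
        of treatment components is LOO-selected over
        ``config.k_range_treatment`` unless ``k`` is given.
        """
        if any(self.is_treatment):
            raise ValueError("model already has treatment components")
        grid = _check_shared_grid(treated_histograms)
        if grid != self.grid:
            raise ValueError("treated histograms are on a different grid")
        cfg = self.config
        H = _as_matrix(treated_histograms)
        ids = [h.tumor_id for h in treated_histograms]
        fixed_P = self.control_P
        root = np.random.SeedSequence(seed)
        sel_seed, fit_seed = [int(s.generate_state(1)[0] % (2**31)) for s in root.spawn(2)]

        def support_builder(H_train: np.ndarray, rng: np.random.Generator):
            return _treatment_support(
                H_train, fixed_P, grid.n_bins, grid.n_visits, cfg, rng
            )

        reports: dict[int, _sel.SufficiencyReport] = {}
        sufficient = True
        if k is None:
            if len(treated_histograms) >= 3:
                k, reports, sufficient = _sel.loo_select(
                    H, cfg.k_range_treatment, sel_seed, cfg.restarts,
                    fixed_P=fixed_P, threshold=cfg.sufficiency_threshold,
                    floor=cfg.chi2_floor, max_iter=cfg.max_iter, tol=cfg.tol,
                    tumor_ids=ids, support_builder=support_builder,
                )
            else:
                k = max(cfg.k_range_treatment)

        rng = np.random.Generator(np.random.PCG64(fit_seed))
        n_frozen = fixed_P.shape[1]
        support = None
        if k > 0:
            support = support_builder(H, rng)
            if support.sum() < k:
                k = 0  # no demonstrable treatment excess anywhere
                support = None
        if k == 0:
            Q = np.column_stack(
                [_em.fit_weights(fixed_P, H[:, j])[0] for j in range(H.shape[1])]
            )
            res_P = fixed_P
            loglik = float(
                sum(
                    _em.poisson_loglik(H[:, j], fixed_P @ Q[:, j])
                    for j in range(H.shape[1])
                )
            )
            history = np.asarray([loglik])
        else:
            res = _em.em_fit(
                H, k, rng, restarts=cfg.restarts, fixed_P=fixed_P,
                max_iter=cfg.max_iter, tol=cfg.tol, support=support,
            )
            res_P, Q, loglik, history = res.P, res.Q, res.loglik, res.loglik_history
        P, Q = _merge_degenerate(res_P.copy(), Q, n_frozen, cfg.merge_cosine)
        components = [
            PMFComponent(c.probs, CONTROL)
            for c in self.components
        ] + [
            PMFComponent(P[:, i].copy(), TREATMENT)
            for i in range(n_frozen, P.shape[1])
        ]
        return LPMResults(
            grid=self.grid,
            components=components,
            training_weights=pd.DataFrame(
                Q.T, index=ids, columns=_component_names(components)
            ),
            loglik=loglik,
            loglik_history=history,
            selection_reports=reports,
            sufficient=sufficient and self.sufficient,
            seed=seed,
            config=cfg,
            training_ids=ids,
            control_histograms=self.control_histograms,
        )

    # -- per-tumor inference --------------------------------------------------
    def fit_tumor(self, h: TumorHistogram) -> "TumorFitResults":
        """Weights-only EM refit of one tumor against the fixed PMFs."""
        if h.grid != self.grid:
            raise ValueError("histogram grid does not match the model grid")
        P = self.P
        q, history, excess = _em.fit_weights(
            P, h.flat, max_iter=self.config.max_iter
        )
        cov = _em.weight_covariance(P, q, h.flat)
        expected = P @ q
        chi2 = _sel.chi2_per_df(
            h.flat, expected, self.n_components, self.config.chi2_floor
        )
        return TumorFitResults(
            model=self,
            histogram=h,
            weights=q,
            weight_covariance=cov,
            chi2_per_df=chi2,
            expected_counts=expected,
            unexplained_count=excess,
            loglik_history=history,
        )

    def training_fit_report(self) -> _sel.SufficiencyReport:
        """Pooled training-data sufficiency: fit value over all control
        tumors refitted against the final model, plus the Bland-Altman
        residual check."""
        if not self.control_histograms:
            raise ValueError("control histograms were not retained")
        obs_all, exp_all = [], []
        chi2_sum = df_sum = 0.0
        for h in self.control_histograms:
            fit = self.fit_tumor(h)
            o, e, _ = _sel.pool_bins(
                h.flat, fit.expected_counts, self.config.chi2_floor
            )
            obs_all.append(o)
            exp_all.append(e)
            chi2_sum += float(np.sum((o - e) ** 2 / e))
            df_sum += o.size - self.n_components
        obs = np.concatenate(obs_all)
        exp = np.concatenate(exp_all)
        ba = _sel.bland_altman_check(obs, exp, floor=0.0)
        rep = _sel.SufficiencyReport(
            k=self.n_components,
            fit_value=float(np.sqrt(chi2_sum / max(df_sum, 1.0))),
            bland_altman=ba,
            threshold=self.config.sufficiency_threshold,
        )
        rep.sufficient = rep.fit_value <= rep.threshold and ba.passed
        return rep

    # -- serialization ----------------------------------------------------
    def to_json(self, path=None) -> str:
        doc = {
            "grid": {
                "adc_edges": self.grid.adc_edges.tolist(),
                "visits": list(self.grid.visits),
            },
            "components": [
                {"class_label": c.class_label, "probs": c.probs.tolist()}
                for c in self.components
            ],
            "metadata": {
                "seed": self.seed,
                "restarts": self.config.restarts,
                "loglik": self.loglik,
                "sufficient": self.sufficient,
                "training_ids": self.training_ids,
            },
        }
        text = json.dumps(doc, sort_keys=True, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "LPMResults":
        if isinstance(source, str) and source.lstrip().startswith("{"):
            doc = json.loads(source)
        else:
            with open(source) as fh:
                doc = json.load(fh)
        grid = BinGrid(
            np.asarray(doc["grid"]["adc_edges"]), tuple(doc["grid"]["visits"])
        )
        components = [
            PMFComponent(np.asarray(c["probs"]), c["class_label"])
            for c in doc["components"]
        ]
        meta = doc.get("metadata", {})
        return cls(
            grid=grid,
            components=components,
            training_weights=pd.DataFrame(),
            loglik=float(meta.get("loglik", np.nan)),
            loglik_history=np.asarray([]),
            selection_reports={},
            sufficient=bool(meta.get("sufficient", True)),
            seed=int(meta.get("seed", 0)),
            config=LPMConfig(),
            training_ids=list(meta.get("training_ids", [])),
        )

    def summary(self) -> str:
        lines = [
            "Linear Poisson Model",
            "====================",
            f"grid: {self.grid.n_bins} bins x {self.grid.n_visits} visit(s) "
            f"{list(self.grid.visits)}",
            f"components: {self.n_components} "
            f"({int((~self.is_treatment).sum())} control, "
            f"{int(self.is_treatment.sum())} treatment)",
            f"training log-likelihood: {self.loglik:.2f}",
            f"sufficient: {self.sufficient}",
        ]
        if not self.training_weights.empty:
            share = self.training_weights.sum(axis=0)
            share = share / share.sum()
            lines.append("component mass shares:")
            for name, s in share.items():
                lines.append(f"  {name}: {s:.3f}")
        return "\n".join(lines)


@dataclass
class TumorFitResults:
    """Per-tumor weights-only fit against a trained model."""

    model: LPMResults
    histogram: TumorHistogram
    weights: np.ndarray
    weight_covariance: np.ndarray
    chi2_per_df: float
    expected_counts: np.ndarray
    unexplained_count: float
    loglik_history: np.ndarray

    @property
    def fit_value(self) -> float:
        """sqrt(chi^2 per degree of freedom)."""
        return float(np.sqrt(self.chi2_per_df))

    @property
    def QT(self) -> float:
        """Voxels attributed to treatment components."""
        return float(self.weights[self.model.is_treatment].sum())

    @property
    def QC(self) -> float:
        """Voxels attributed to control components."""
        return float(self.weights[~self.model.is_treatment].sum())

    def assess(self, z_threshold: float = 3.0):
        from .inference import assess_response

        return assess_response(self.model, self, z_threshold=z_threshold)

    def summary(self) -> str:
        a = self.assess()
        lines = [
            f"Tumor {self.histogram.tumor_id} ({self.histogram.cohort})",
            f"  total voxels: {self.histogram.total}",
            f"  QT = {a.QT:.1f} +/- {a.sigma_QT:.1f}   QC = {a.QC:.1f}",
            f"  Z = {a.z:.2f}   p = {a.p_value:.3g}   responder: {a.responder}",
            f"  fit value sqrt(chi2/df) = {self.fit_value:.3f}",
        ]
        if self.unexplained_count:
            lines.append(
                f"  WARNING: {self.unexplained_count:.0f} voxels in bins "
                "without model support"
            )
        return "\n".join(lines)
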