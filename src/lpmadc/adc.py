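"""Voxel-wise ADC estimation from multi-b diffusion-weighted signals.

The signal model is the mono-exponential decay ``S = S0 * exp(-b * D)``
with ``b`` the diffusion weighting (s/mm^2) and ``D`` the apparent
diffusion coefficient (mm^2/s).  The default estimator is linear least
squares on log-signal, which is deterministic and exact for noiseless
data; a nonlinear least-squares option is available for robustness
comparisons.  Negative fitted diffusivities (possible under noise) are
clipped to zero and flagged rather than propagated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy.optimize import curve_fit

__all__ = ["BValueSignal", "ADCFit", "VoxelGeometry", "fit_adc_voxel", "voxel_volume",
           "extract_masked_adc"]


class BValueSignal(NamedTuple):
    """One diffusion-weighted measurement: weighting ``b`` (s/mm^2) and
    positive signal intensity ``S`` (arbitrary units)."""

    b: float
    S: float


class ADCFit(NamedTuple):
    adc: float  #: fitted D, mm^2/s (clipped at 0)
    clipped: bool  #: True when the raw fit was negative


@dataclass(frozen=True)
class VoxelGeometry:
    """Acquisition voxel dimensions in mm."""

    in_plane_x: float
    in_plane_y: float
    slice_thickness: float

    def __post_init__(self) -> None:
        if min(self.in_plane_x, self.in_plane_y, self.slice_thickness) <= 0:
            raise ValueError("voxel dimensions must be strictly positive")


def voxel_volume(g: VoxelGeometry) -> float:
    """Voxel volume in mm^3 (product of the three dimensions)."""
    return g.in_plane_x * g.in_plane_y * g.slice_thickness


def fit_adc_voxel(
    signals: Sequence[BValueSignal], method: str = "linear"
) -> ADCFit:
    """Estimate the apparent diffusion coefficient for one voxel.

    Parameters
    ----------
    signals
        Measurements at >= 2 distinct b values; all signals must be > 0.
    method
        ``"linear"`` (default): least squares on ``log S = log S0 - b D``.
        ``"nonlinear"``: Levenberg-Marquardt on the exponential directly,
        initialised from the linear fit.

    Returns
    -------
    ADCFit
        Fitted D (mm^2/s, clipped below at 0) and a flag marking clipping.
    """
    b = np.asarray([s.b for s in signals], dtype=float)
    S = np.asarray([s.S for s in signals], dtype=float)
    if np.any(b < 0):
        raise ValueError("b values must be nonnegative")
    if np.any(S <= 0):
        raise ValueError("signal intensities must be strictly positive")
    if np.unique(b).size < 2:
        raise ValueError("at least 2 distinct b values are required")

    # slope of log-signal against b; D = -slope
    slope, _ = np.polyfit(b, np.log(S), 1)
    d = -slope
    if method == "nonlinear":
        s0 = float(np.exp(np.log(S).mean() + d * b.mean()))

        def model(bv, s0_, d_):
            return s0_ * np.exp(-bv * d_)

        try:
            popt, _ = curve_fit(model, b, S, p0=[s0, max(d, 0.0)], maxfev=5000)
            d = float(popt[1])
        except RuntimeError:
            pass  # fall back to the linear estimate
    elif method != "linear":
        raise ValueError(f"unknown method {method!r}")

    if d < 0:
        return ADCFit(0.0, True)
    if d < 1e-15:  # numerically flat decay
        d = 0.0
    return ADCFit(float(d), False)


def extract_masked_adc(adc_path, mask_path) -> np.ndarray:
    """Extract masked voxel ADC values from a NIfTI ADC volume + binary mask.

    Voxels where the mask is nonzero are returned as a flat array of ADC
    values (mm^2/s).  Shapes must match.
    """
    import nibabel as nib

    adc_img = nib.load(str(adc_path))
    mask_img = nib.load(str(mask_path))
    adc = np.asanyarray(adc_img.dataobj, dtype=float)
    mask = np.asanyarray(mask_img.dataobj)
    if adc.shape != mask.shape:
        raise ValueError(
            f"ADC volume shape {adc.shape} != mask shape {mask.shape}"
        )
    return adc[mask != 0].ravel()
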