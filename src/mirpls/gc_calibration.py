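"""Internal-standard GC-FID calibration for ethanol.

The reference method quantifies ethanol from the peak-area ratio of
ethanol to n-propanol (added at fixed concentration as internal standard,
cancelling injection-volume variability).  The calibration curve is an
ordinary least-squares line, area_ratio = slope * conc + intercept, fitted
over standards spanning 1-50 % w/w; detection and quantification limits
follow the 3-sigma / 10-sigma residual rule:

    LOD = 3 * sigma_res / |slope|,    LOQ = 10 * sigma_res / |slope|

with sigma_res the residual standard deviation of the regression (n - 2
degrees of freedom).

A separate affine map converts % w/w to % v/v.  The default coefficients
(1.21879, 0.13712) are an empirical fit and carry a small non-physical
intercept at zero concentration; a density-based conversion is provided as
an explicit alternative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exceptions import DegenerateDataError, DomainError

#: Empirical % w/w -> % v/v conversion line (slope, intercept).
WW_TO_VV_SLOPE = 1.21879
WW_TO_VV_INTERCEPT = 0.13712

#: Densities (g/mL, 20 C) for the physically-motivated conversion.
ETHANOL_DENSITY = 0.78934


@dataclass(frozen=True)
class CalibrationCurve:
    """OLS internal-standard line with its figures of merit."""

    slope: float              # area-ratio per % w/w
    intercept: float          # area-ratio
    r2: float
    residual_sigma: float     # area-ratio units, n-2 dof
    n_points: int

    @property
    def lod(self) -> float:
        """Limit of detection, % w/w (3-sigma rule)."""
        return 3.0 * self.residual_sigma / abs(self.slope)

    @property
    def loq(self) -> float:
        """Limit of quantification, % w/w (10-sigma rule)."""
        return 10.0 * self.residual_sigma / abs(self.slope)

    def area_ratio_at(self, conc_ww: float) -> float:
        return self.slope * conc_ww + self.intercept


#: The published reference curve, usable as a generating truth in simulations.
REFERENCE_CURVE = CalibrationCurve(
    slope=0.13903, intercept=0.04488, r2=0.9992, residual_sigma=0.0, n_points=6
)


def fit_curve(concentrations, area_ratios) -> CalibrationCurve:
    """Least-squares calibration line from standards.

    Needs at least 3 points with non-zero concentration spread so the
    residual sigma has its n-2 degrees of freedom.
    """
    x = np.asarray(concentrations, dtype=float).ravel()
    y = np.asarray(area_ratios, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError(f"length mismatch: {x.size} concentrations vs {y.size} ratios")
    if x.size < 3:
        raise DegenerateDataError(f"calibration needs >= 3 points, got {x.size}")
    if np.ptp(x) == 0:
        raise DegenerateDataError("zero concentration spread")
    res = stats.linregress(x, y)
    residuals = y - (res.slope * x + res.intercept)
    sigma = float(np.sqrt(np.sum(residuals**2) / (x.size - 2)))
    return CalibrationCurve(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=float(res.rvalue**2),
        residual_sigma=sigma,
        n_points=int(x.size),
    )


def quantify(curve: CalibrationCurve, area_ratio: float) -> tuple[float, bool]:
    """Invert the curve: concentration = (ratio - intercept)/slope.

    Returns (concentration % w/w, below_zero flag).  Negative results are
    reported as-is with the flag set, never clipped — clipping would hide
    a blank or baseline problem.
    """
    if curve.slope == 0:
        raise DomainError("calibration slope is zero; curve unusable")
    conc = (float(area_ratio) - curve.intercept) / curve.slope
    return conc, conc < 0


def lod_loq(curve: CalibrationCurve) -> tuple[float, float]:
    """(LOD, LOQ) in % w/w; their ratio is 10/3 by construction."""
    return curve.lod, curve.loq


def ww_to_vv(conc_ww: float) -> float:
    """Convert % w/w to % v/v with the empirical affine map."""
    if np.any(np.asarray(conc_ww) < 0):
        raise DomainError("concentration must be non-negative")
    return WW_TO_VV_SLOPE * conc_ww + WW_TO_VV_INTERCEPT


def vv_to_ww(conc_vv: float) -> float:
    """Inverse of :func:`ww_to_vv`."""
    return (conc_vv - WW_TO_VV_INTERCEPT) / WW_TO_VV_SLOPE


def ww_to_vv_density(conc_ww: float, sample_density: float = 0.9819) -> float:
    """Density-based alternative conversion (zero maps to zero).

    % v/v = % w/w * rho_sample / rho_ethanol, with the sample density in
    g/mL.  The default sample density approximates a dilute aqueous
    ethanol matrix; pass the measured density for accurate work.
    """
    if sample_density <= 0:
        raise DomainError("sample density must be positive")
    return conc_ww * sample_density / ETHANOL_DENSITY
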