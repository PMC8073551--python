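"""Bacterial growth calibration and MOI dosing.

An overnight-diluted culture is sampled hourly for optical density at
600 nm (OD600) and viable counts (CFU/mL).  Within the exponential window
(2-5 h by default) the two track each other linearly, so an ordinary
least-squares line ``CFU/mL = slope * OD600 + intercept`` calibrates the
quick OD measurement to a cell density.  The calibration is then used to
dose a co-culture: for a target multiplicity of infection (MOI, bacteria
per host cell) the required volume of culture is

    cfu_needed = moi * n_cells
    volume_ml  = cfu_needed / (slope * od600 + intercept)
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .errors import CalibrationError, ValidationError

__all__ = ["GrowthCalibration", "calibrate_growth", "moi_dose"]

#: exponential-phase window, hours after dilution
DEFAULT_WINDOW = (2.0, 5.0)


@dataclass
class GrowthCalibration:
    """Linear OD600 -> CFU/mL map fitted on the exponential window."""

    slope: float            # CFU/mL per OD unit
    intercept: float        # CFU/mL
    r_squared: float
    window: tuple[float, float]
    n_points: int

    def predict_cfu_per_ml(self, od600: float) -> float:
        return self.slope * od600 + self.intercept

    def as_record(self) -> dict:
        return asdict(self)


def calibrate_growth(table: pd.DataFrame,
                     window: tuple[float, float] = DEFAULT_WINDOW,
                     zero_intercept: bool = False) -> GrowthCalibration:
    """Fit CFU/mL on OD600 by least squares within the exponential window.

    ``table`` needs columns ``time_h, od600, cfu_per_ml``.  Rows outside
    ``window`` (inclusive) never influence the fit.  With
    ``zero_intercept=True`` the line is forced through the origin (a pure
    OD-to-CFU ratio); r-squared is then computed about zero.
    """
    required = {"time_h", "od600", "cfu_per_ml"}
    if not required.issubset(table.columns):
        raise ValidationError(f"growth table must have columns {sorted(required)}")
    lo, hi = window
    rows = table[(table["time_h"] >= lo) & (table["time_h"] <= hi)]
    od = rows["od600"].to_numpy(dtype=float)
    cfu = rows["cfu_per_ml"].to_numpy(dtype=float)
    if np.unique(od).size < 2:
        raise CalibrationError(
            f"need at least 2 distinct OD600 values inside window {window}, "
            f"got {np.unique(od).size}")

    if zero_intercept:
        slope = float(od @ cfu / (od @ od))
        intercept = 0.0
        resid = cfu - slope * od
        tss = float(cfu @ cfu)  # uncentered: variation about zero
    else:
        res = stats.linregress(od, cfu)
        slope, intercept = float(res.slope), float(res.intercept)
        resid = cfu - (slope * od + intercept)
        tss = float(np.sum((cfu - cfu.mean()) ** 2))
    rss = float(resid @ resid)
    r2 = 1.0 if tss == 0.0 else max(0.0, min(1.0, 1.0 - rss / tss))
    return GrowthCalibration(slope=slope, intercept=intercept, r_squared=r2,
                             window=(float(lo), float(hi)), n_points=od.size)


def moi_dose(calibration: GrowthCalibration, od600: float, n_cells: float,
             moi: float = 0.005) -> tuple[float, float]:
    """Bacteria and culture volume needed for a target MOI.

    Returns ``(cfu_needed, volume_ml)`` where ``cfu_needed = moi * n_cells``
    and the volume is taken from a culture whose density is predicted from
    the measured OD600 via the calibration.  The default MOI of 0.005
    bacteria per host cell matches a gentle co-culture inoculum.
    """
    if n_cells <= 0:
        raise ValidationError("n_cells must be positive")
    if moi <= 0:
        raise ValidationError("moi must be positive")
    density = calibration.predict_cfu_per_ml(od600)
    if density <= 0:
        raise CalibrationError(
            f"predicted culture density is non-positive ({density:g} CFU/mL "
            f"at OD600={od600}); cannot dose")
    cfu_needed = moi * n_cells
    return cfu_needed, cfu_needed / density
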