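"""Fixed-timepoint expression comparisons with Sidak correction.

Late samples (24, 48 and 72 h) fall outside the rhythm-fitting window and
are compared directly between conditions: a two-sample t-test per
gene x timepoint x condition pair (pooled variance by default, Welch on
request), Sidak-corrected within each gene x timepoint family, with the
usual significance labels:

    ns for p > 0.05, * for p <= 0.05, ** for p <= 0.01,
    *** for p <= 0.001 and **** for p <= 0.0001
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError

__all__ = ["EndpointComparison", "significance_label", "compare_endpoints"]

DEFAULT_TIMEPOINTS = (24.0, 48.0, 72.0)

_LABEL_THRESHOLDS = ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (5e-2, "*"))


def significance_label(p: float) -> str:
    """Asterisk label for an (adjusted) p-value; boundaries are inclusive."""
    for threshold, label in _LABEL_THRESHOLDS:
        if p <= threshold:
            return label
    return "ns"


@dataclass
class EndpointComparison:
    """One two-sample comparison at a fixed timepoint."""

    gene: str
    timepoint: float
    condition_a: str
    condition_b: str
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    n_a: int
    n_b: int
    t_statistic: float
    p_raw: float
    p_sidak: float
    family_size: int
    significance_label: str

    def as_record(self) -> dict:
        return asdict(self)


def compare_endpoints(series: pd.DataFrame,
                      pairs: Sequence[tuple[str, str]],
                      timepoints: Sequence[float] = DEFAULT_TIMEPOINTS,
                      welch: bool = False) -> pd.DataFrame:
    """Pairwise condition comparisons of expression at fixed timepoints.

    ``series`` is the long-format table ``gene, condition, time_h, value``.
    For every gene and timepoint, each requested condition pair is tested
    with a two-sample t-test; Sidak correction uses the number of pairs
    actually tested within that gene x timepoint as the family size.
    Cells with fewer than 2 observations are skipped with a warning.
    """
    if not pairs:
        raise ValidationError("at least one condition pair is required")
    out: list[EndpointComparison] = []
    for (gene, t), grp in series[series["time_h"].isin(timepoints)].groupby(
            ["gene", "time_h"], sort=True):
        cell: list[tuple[tuple[str, str], np.ndarray, np.ndarray]] = []
        for a, b in pairs:
            ya = grp.loc[grp["condition"] == a, "value"].to_numpy(dtype=float)
            yb = grp.loc[grp["condition"] == b, "value"].to_numpy(dtype=float)
            if ya.size < 2 or yb.size < 2:
                warnings.warn(
                    f"skipping {gene} at {t} h, {a} vs {b}: "
                    f"needs >= 2 observations per group", stacklevel=2)
                continue
            cell.append(((a, b), ya, yb))
        m = len(cell)
        for (a, b), ya, yb in cell:
            tt = stats.ttest_ind(ya, yb, equal_var=not welch)
            p_raw = float(tt.pvalue)
            p_sidak = float(1.0 - (1.0 - p_raw) ** m)
            out.append(EndpointComparison(
                gene=str(gene), timepoint=float(t),
                condition_a=a, condition_b=b,
                mean_a=float(ya.mean()), mean_b=float(yb.mean()),
                sd_a=float(ya.std(ddof=1)), sd_b=float(yb.std(ddof=1)),
                n_a=ya.size, n_b=yb.size,
                t_statistic=float(tt.statistic),
                p_raw=p_raw, p_sidak=p_sidak, family_size=m,
                significance_label=significance_label(p_sidak)))
    return pd.DataFrame([c.as_record() for c in out])
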