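"""Single-component cosinor rhythmometry.

Fits the linear model

    Y = alpha * sin(2*pi*t/tau) + beta * cos(2*pi*t/tau) + gamma

to a time course of (relative) expression values by ordinary least squares,
derives the rhythm parameters

    amplitude  A     = sqrt(alpha**2 + beta**2)
    acrophase  theta = atan2(-alpha, beta), wrapped into (-2*pi, 0]

so that the fitted curve equals ``gamma + A*cos(2*pi*t/tau + theta)``, and
tests for rhythmicity with the zero-amplitude F-test: the nested-model
comparison of the cosinor fit against an intercept-only fit, with
(2, n - 3) degrees of freedom.

The period ``tau`` is fixed (24 h by default); no period estimation is
attempted.  Replicates and independent experiments are pooled as independent
observations in a single regression.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .errors import FitError, ValidationError

__all__ = [
    "CosinorFit",
    "design_matrix",
    "acrophase",
    "peak_time",
    "fit_cosinor",
    "zero_amplitude_test",
    "fit_series",
]

TWO_PI = 2.0 * math.pi

#: minimum observations for the 3-parameter model plus one residual df
_MIN_OBS = 4


def design_matrix(times: np.ndarray, period: float = 24.0) -> np.ndarray:
    """Cosinor design matrix with columns (sin, cos, 1).

    Row i is ``(sin(2*pi*t_i/period), cos(2*pi*t_i/period), 1)``.
    """
    if period <= 0:
        raise ValidationError(f"period must be positive, got {period}")
    t = np.asarray(times, dtype=float)
    if not np.all(np.isfinite(t)):
        raise ValidationError("times must be finite")
    omega_t = TWO_PI * t / period
    return np.column_stack([np.sin(omega_t), np.cos(omega_t), np.ones_like(t)])


def acrophase(alpha: float, beta: float) -> float:
    """Acrophase angle in radians, wrapped into (-2*pi, 0].

    The acrophase is the unique angle theta with ``beta = A*cos(theta)`` and
    ``alpha = -A*sin(theta)``, i.e. ``theta = atan2(-alpha, beta)``; the peak
    of the fitted cosine occurs at ``t = -theta*period/(2*pi)``.  When both
    coefficients are zero (flat signal) 0.0 is returned by convention.
    """
    if alpha == 0.0 and beta == 0.0:
        return 0.0
    theta = math.atan2(-alpha, beta)  # in (-pi, pi]
    if theta > 0.0:
        theta -= TWO_PI
    if theta <= -TWO_PI:  # guard the open endpoint against rounding
        theta = 0.0
    return theta


def peak_time(theta: float, period: float = 24.0) -> float:
    """Clock time of the fitted peak in [0, period) for acrophase ``theta``."""
    return (-theta) * period / TWO_PI % period


@dataclass
class CosinorFit:
    """Cosinor fit for one gene x condition slice.

    ``alpha`` and ``beta`` are the sine and cosine coefficients, ``mesor``
    the rhythm-adjusted mean (intercept).  ``p_value`` is the zero-amplitude
    F-test p-value; ``p_adjusted`` is filled in by :func:`fit_series` when a
    whole table is analysed, otherwise it equals ``p_value``.
    """

    gene: str | None
    condition: str | None
    period: float
    alpha: float
    beta: float
    mesor: float
    amplitude: float
    acrophase: float
    peak_time: float
    n_obs: int
    rss_full: float
    rss_reduced: float
    F_statistic: float
    p_value: float
    p_adjusted: float | None = None
    degenerate: bool = field(default=False)
    #: coefficient covariance (3x3, order alpha/beta/mesor); excluded from tables
    cov: np.ndarray | None = field(default=None, repr=False, compare=False)

    def as_record(self) -> dict:
        d = asdict(self)
        d.pop("cov")
        return d


def _rss_tolerance(y: np.ndarray) -> float:
    return 1e-12 * max(1.0, float(np.sum(y * y)))


def _f_test(rss_full: float, rss_reduced: float, df_num: int, df_den: int,
            tol: float) -> tuple[float, float, bool]:
    """Nested-model F-test with degenerate-fit conventions.

    A perfect full fit with signal (``rss_full ~ 0 < rss_reduced``) yields
    p = 0; a perfect reduced fit (no improvement possible) yields p = 1.
    Both are flagged as degenerate rather than silently clipped.
    """
    if rss_reduced <= tol:
        return 0.0, 1.0, True
    if rss_full <= tol:
        return math.inf, 0.0, True
    F = ((rss_reduced - rss_full) / df_num) / (rss_full / df_den)
    F = max(F, 0.0)
    p = float(stats.f.sf(F, df_num, df_den))
    return F, p, False


def fit_cosinor(times, values, period: float = 24.0,
                gene: str | None = None,
                condition: str | None = None) -> CosinorFit:
    """Fit the single-component cosinor model to one slice by least squares.

    Parameters
    ----------
    times, values
        Observation times in hours and expression values; replicates appear
        as repeated time points.
    period
        Fixed period in hours (default 24).

    Raises
    ------
    FitError
        If fewer than 4 observations are available or the design is
        rank-deficient (e.g. all observations at a single time point).
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.shape != y.shape or t.ndim != 1:
        raise ValidationError("times and values must be 1-d arrays of equal length")
    if not np.all(np.isfinite(y)):
        raise ValidationError("expression values must be finite")
    n = t.size
    if n < _MIN_OBS:
        raise FitError(
            f"cosinor fit needs at least {_MIN_OBS} observations, got {n}"
            + (f" (gene={gene}, condition={condition})" if gene else "")
        )
    X = design_matrix(t, period)
    if np.linalg.matrix_rank(X) < 3:
        raise FitError(
            "rank-deficient cosinor design: need at least 3 distinct time points "
            "that are not collinear in (sin, cos, 1)"
            + (f" (gene={gene}, condition={condition})" if gene else "")
        )
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    alpha, beta, gamma = (float(c) for c in coef)
    resid = y - X @ coef
    rss_full = float(resid @ resid)
    rss_reduced = float(np.sum((y - y.mean()) ** 2))

    tol = _rss_tolerance(y)
    F, p, degenerate = _f_test(rss_full, rss_reduced, 2, n - 3, tol)

    sigma2 = rss_full / (n - 3)
    cov = sigma2 * np.linalg.inv(X.T @ X)

    A = math.hypot(alpha, beta)
    theta = acrophase(alpha, beta)
    return CosinorFit(
        gene=gene, condition=condition, period=period,
        alpha=alpha, beta=beta, mesor=gamma,
        amplitude=A, acrophase=theta, peak_time=peak_time(theta, period),
        n_obs=n, rss_full=rss_full, rss_reduced=rss_reduced,
        F_statistic=F, p_value=p, p_adjusted=p, degenerate=degenerate,
        cov=cov,
    )


def zero_amplitude_test(fit: CosinorFit) -> tuple[float, float]:
    """Zero-amplitude rhythmicity F-test for a fitted slice.

    Recomputes ``F = ((RSS0 - RSS1)/2) / (RSS1/(n-3))`` from the residual
    sums of squares stored on the fit and returns ``(F, p)`` with p from the
    upper tail of F(2, n-3).
    """
    if fit.n_obs <= 3:
        raise FitError("zero-amplitude test needs n > 3")
    # scale-aware degeneracy tolerance reconstructed from the stored RSS
    tol = 1e-12 * max(1.0, fit.rss_reduced, fit.rss_full)
    F, p, _ = _f_test(fit.rss_full, fit.rss_reduced, 2, fit.n_obs - 3, tol)
    return F, p


def fit_series(series: pd.DataFrame, period: float = 24.0,
               max_time: float | None = None,
               adjust: str = "benjamini-hochberg") -> pd.DataFrame:
    """Fit every gene x condition slice of a long-format expression table.

    ``series`` must have columns ``gene, condition, time_h, value`` (an
    ``experiment`` column is allowed and pooled).  Rhythmicity p-values are
    adjusted across all slices in one family with the requested method.
    ``max_time`` restricts the fit to early time points (the late 48/72 h
    samples are endpoint data, not part of the rhythm window).
    """
    from .differential import adjust_pvalues  # local import to avoid cycle

    df = series if max_time is None else series[series["time_h"] <= max_time]
    fits: list[CosinorFit] = []
    for (gene, condition), grp in df.groupby(["gene", "condition"], sort=True):
        fits.append(fit_cosinor(grp["time_h"].to_numpy(), grp["value"].to_numpy(),
                                period=period, gene=str(gene), condition=str(condition)))
    if fits:
        adj = adjust_pvalues([f.p_value for f in fits], method=adjust)
        for f, q in zip(fits, adj):
            f.p_adjusted = q
    return pd.DataFrame([f.as_record() for f in fits])
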