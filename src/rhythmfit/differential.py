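"""Two-condition differential rhythmicity.

Extends the cosinor model with a condition indicator g (0 for control,
1 for the perturbed culture):

    Y = (alpha1 + g*alpha2) * X1 + (beta1 + g*beta2) * X2 + gamma

so that (alpha2, beta2) carry the waveform change between conditions.  The
joint null (alpha2, beta2) = (0, 0) is tested with a nested F-test against
the pooled single-condition cosinor; amplitude change and acrophase shift
get parameter-level p-values through delta-method standard errors on the
OLS coefficient covariance.

Conventions
-----------
* ``phase_shift_hours`` is positive when the perturbed condition peaks
  EARLIER than control (a phase advance), wrapped into (-tau/2, tau/2].
* By default the mesor (intercept) is shared between conditions as in the
  stacked model above; ``shared_mesor=False`` adds a condition-specific
  intercept term ``gamma2 * g``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .cosinor import TWO_PI, acrophase, design_matrix, _rss_tolerance, _f_test
from .errors import FitError, ValidationError

__all__ = [
    "DifferentialFit",
    "fit_differential",
    "differential_significance",
    "adjust_pvalues",
    "wrap_hours",
    "compare_series",
]


def wrap_hours(delta: float, period: float = 24.0) -> float:
    """Wrap an hour difference into the half-open interval (-period/2, period/2]."""
    h = (delta + period / 2.0) % period - period / 2.0
    if h <= -period / 2.0:
        h += period
    return h


@dataclass
class DifferentialFit:
    """Differential-rhythmicity fit for one gene and one condition pair."""

    gene: str | None
    control: str
    perturbed: str
    period: float
    alpha1: float
    beta1: float
    alpha2: float
    beta2: float
    mesor: float
    mesor_perturbed: float  # equals mesor when the intercept is shared
    shared_mesor: bool
    amplitude_control: float
    amplitude_perturbed: float
    amplitude_change: float          # A_perturbed - A_control
    amplitude_fold: float            # A_perturbed / A_control (inf if A_control=0)
    acrophase_control: float
    acrophase_perturbed: float
    phase_shift_hours: float         # positive = advance (earlier peak)
    n_obs: int
    rss_full: float
    rss_reduced: float
    F_statistic: float = math.nan
    p_differential_rhythmicity: float = math.nan
    p_amplitude: float = math.nan
    p_phase: float = math.nan
    p_differential_adjusted: float | None = None
    p_amplitude_adjusted: float | None = None
    p_phase_adjusted: float | None = None
    degenerate: bool = False
    cov: np.ndarray | None = field(default=None, repr=False, compare=False)

    def as_record(self) -> dict:
        d = asdict(self)
        d.pop("cov")
        return d


def _stacked_design(t1: np.ndarray, t2: np.ndarray, period: float,
                    shared_mesor: bool) -> tuple[np.ndarray, np.ndarray]:
    t = np.concatenate([t1, t2])
    g = np.concatenate([np.zeros(t1.size), np.ones(t2.size)])
    base = design_matrix(t, period)  # (sin, cos, 1)
    cols = [base[:, 0], base[:, 1], g * base[:, 0], g * base[:, 1], base[:, 2]]
    if not shared_mesor:
        cols.append(g)
    return np.column_stack(cols), g


def fit_differential(times_control, values_control, times_perturbed, values_perturbed,
                     period: float = 24.0, shared_mesor: bool = True,
                     gene: str | None = None,
                     control: str = "control", perturbed: str = "perturbed",
                     ) -> DifferentialFit:
    """Fit the interaction cosinor model on two stacked condition slices.

    Both slices must satisfy the single-condition fit preconditions.  The
    returned fit already carries the joint and parameter-level p-values
    (see :func:`differential_significance`).
    """
    t1 = np.asarray(times_control, dtype=float)
    y1 = np.asarray(values_control, dtype=float)
    t2 = np.asarray(times_perturbed, dtype=float)
    y2 = np.asarray(values_perturbed, dtype=float)
    for t, y in ((t1, y1), (t2, y2)):
        if t.shape != y.shape or t.ndim != 1:
            raise ValidationError("times and values must be 1-d arrays of equal length")
        if t.size < 4:
            raise FitError("each condition slice needs at least 4 observations")

    X, g = _stacked_design(t1, t2, period, shared_mesor)
    y = np.concatenate([y1, y2])
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise FitError(
            "rank-deficient differential design"
            + (f" (gene={gene})" if gene else "")
        )
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    rss_full = float(resid @ resid)

    alpha1, beta1, alpha2, beta2, gamma = (float(c) for c in coef[:5])
    gamma2 = float(coef[5]) if not shared_mesor else 0.0

    # reduced model: no condition-waveform interaction
    Xr = X[:, [0, 1, 4]] if shared_mesor else X[:, [0, 1, 4, 5]]
    coef_r, _, _, _ = np.linalg.lstsq(Xr, y, rcond=None)
    resid_r = y - Xr @ coef_r
    rss_reduced = float(resid_r @ resid_r)

    sigma2 = rss_full / (n - p)
    cov = sigma2 * np.linalg.inv(X.T @ X)

    A1 = math.hypot(alpha1, beta1)
    A2 = math.hypot(alpha1 + alpha2, beta1 + beta2)
    th1 = acrophase(alpha1, beta1)
    th2 = acrophase(alpha1 + alpha2, beta1 + beta2)
    shift_h = wrap_hours((th2 - th1) * period / TWO_PI, period)

    fit = DifferentialFit(
        gene=gene, control=control, perturbed=perturbed, period=period,
        alpha1=alpha1, beta1=beta1, alpha2=alpha2, beta2=beta2,
        mesor=gamma, mesor_perturbed=gamma + gamma2, shared_mesor=shared_mesor,
        amplitude_control=A1, amplitude_perturbed=A2,
        amplitude_change=A2 - A1,
        amplitude_fold=(A2 / A1) if A1 > 0 else math.inf,
        acrophase_control=th1, acrophase_perturbed=th2,
        phase_shift_hours=shift_h,
        n_obs=n, rss_full=rss_full, rss_reduced=rss_reduced,
        cov=cov,
    )
    return differential_significance(fit, _y_scale=float(np.sum(y * y)))


def differential_significance(fit: DifferentialFit,
                              _y_scale: float | None = None) -> DifferentialFit:
    """Attach joint and parameter-level significance to a differential fit.

    The joint test compares the interaction model against the pooled
    single-condition cosinor (restriction alpha2 = beta2 = 0, 2 numerator
    df).  Amplitude-change and phase-shift p-values use delta-method
    standard errors propagated through the coefficient covariance, against
    a two-sided normal reference.  Perfect fits follow the degenerate
    conventions: zero residuals with zero effects give p = 1, zero
    residuals with non-zero effects give p = 0, flagged either way.
    """
    n = fit.n_obs
    p_par = 5 if fit.shared_mesor else 6
    df_den = n - p_par
    if df_den <= 0:
        raise FitError("no residual degrees of freedom for the differential test")
    tol = 1e-12 * max(1.0, _y_scale if _y_scale is not None else fit.rss_reduced)

    effect = math.hypot(fit.alpha2, fit.beta2)
    if fit.rss_full <= tol:
        # perfect fit: significance is decided by whether an effect exists
        fit.degenerate = True
        if effect <= math.sqrt(tol):
            fit.F_statistic = 0.0
            fit.p_differential_rhythmicity = 1.0
            fit.p_amplitude = 1.0
            fit.p_phase = 1.0
        else:
            fit.F_statistic = math.inf
            fit.p_differential_rhythmicity = 0.0
            fit.p_amplitude = 0.0
            fit.p_phase = 0.0
        _fill_adjusted_defaults(fit)
        return fit

    F, p_joint, degen = _f_test(fit.rss_full, fit.rss_reduced, 2, df_den, tol)
    fit.F_statistic = F
    fit.p_differential_rhythmicity = p_joint
    fit.degenerate = degen

    cov = fit.cov[:4, :4] if fit.cov is not None else None
    if cov is None:
        raise FitError("coefficient covariance unavailable; refit required")

    a1, b1, a2, b2 = fit.alpha1, fit.beta1, fit.alpha2, fit.beta2
    A1, A2 = fit.amplitude_control, fit.amplitude_perturbed

    # delta method on A2 - A1; gradient w.r.t. (alpha1, beta1, alpha2, beta2)
    if A1 > 0 and A2 > 0:
        gA = np.array([(a1 + a2) / A2 - a1 / A1,
                       (b1 + b2) / A2 - b1 / A1,
                       (a1 + a2) / A2,
                       (b1 + b2) / A2])
        seA = math.sqrt(max(float(gA @ cov @ gA), 0.0))
        zA = (A2 - A1) / seA if seA > 0 else math.inf * np.sign(A2 - A1 or 1)
        fit.p_amplitude = float(2.0 * stats.norm.sf(abs(zA))) if math.isfinite(zA) else 0.0

        # theta = atan2(-alpha, beta): d/dalpha = -beta/A^2, d/dbeta = alpha/A^2
        gT = np.array([-(b1 + b2) / A2**2 + b1 / A1**2,
                       (a1 + a2) / A2**2 - a1 / A1**2,
                       -(b1 + b2) / A2**2,
                       (a1 + a2) / A2**2])
        seT = math.sqrt(max(float(gT @ cov @ gT), 0.0))
        dtheta = fit.phase_shift_hours * TWO_PI / fit.period  # wrapped difference
        zT = dtheta / seT if seT > 0 else math.inf * np.sign(dtheta or 1)
        fit.p_phase = float(2.0 * stats.norm.sf(abs(zT))) if math.isfinite(zT) else 0.0
    else:
        # an arrhythmic condition has no defined acrophase; fall back on the
        # joint interaction test for both parameter-level questions
        fit.p_amplitude = p_joint
        fit.p_phase = p_joint

    _fill_adjusted_defaults(fit)
    return fit


def _fill_adjusted_defaults(fit: DifferentialFit) -> None:
    if fit.p_differential_adjusted is None:
        fit.p_differential_adjusted = fit.p_differential_rhythmicity
    if fit.p_amplitude_adjusted is None:
        fit.p_amplitude_adjusted = fit.p_amplitude
    if fit.p_phase_adjusted is None:
        fit.p_phase_adjusted = fit.p_phase


def adjust_pvalues(pvalues: Sequence[float],
                   method: str = "benjamini-hochberg") -> list[float]:
    """Multiple-testing adjustment of a p-value family.

    ``benjamini-hochberg``: step-up FDR-adjusted values
    ``q_(i) = min_{j >= i} (m * p_(j) / j)`` capped at 1.
    ``sidak``: family-wise ``1 - (1 - p)**m``.
    """
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    method = method.lower().replace("_", "-")
    if method in ("benjamini-hochberg", "bh", "fdr-bh"):
        return list(multipletests(p, method="fdr_bh")[1])
    if method in ("sidak",):
        return list(1.0 - (1.0 - p) ** p.size)
    raise ValidationError(f"unknown adjustment method: {method!r}")


def compare_series(series: pd.DataFrame, control: str, perturbed: str | Sequence[str],
                   period: float = 24.0, shared_mesor: bool = True,
                   max_time: float | None = None,
                   adjust: str = "benjamini-hochberg") -> pd.DataFrame:
    """Differential fits for every gene, control vs. each perturbed condition.

    ``series`` is the long-format table with columns
    ``gene, condition, time_h, value``.  Each p-value type (joint,
    amplitude, phase) is adjusted in its own family across all
    genes x condition pairs.
    """
    if isinstance(perturbed, str):
        perturbed = [perturbed]
    df = series if max_time is None else series[series["time_h"] <= max_time]
    present = set(df["condition"].unique())
    missing = ({control} | set(perturbed)) - present
    if missing:
        raise ValidationError(f"conditions not found in data: {sorted(missing)}")

    fits: list[DifferentialFit] = []
    for pert in perturbed:
        for gene, grp in df[df["condition"].isin([control, pert])].groupby("gene", sort=True):
            c = grp[grp["condition"] == control]
            x = grp[grp["condition"] == pert]
            fits.append(fit_differential(
                c["time_h"].to_numpy(), c["value"].to_numpy(),
                x["time_h"].to_numpy(), x["value"].to_numpy(),
                period=period, shared_mesor=shared_mesor,
                gene=str(gene), control=control, perturbed=pert))
    if fits:
        for raw, adj in (("p_differential_rhythmicity", "p_differential_adjusted"),
                         ("p_amplitude", "p_amplitude_adjusted"),
                         ("p_phase", "p_phase_adjusted")):
            qs = adjust_pvalues([getattr(f, raw) for f in fits], method=adjust)
            for f, q in zip(fits, qs):
                setattr(f, adj, q)
    return pd.DataFrame([f.as_record() for f in fits])
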