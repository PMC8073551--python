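"""Synthetic data generation for the full analysis chain.

Every downstream estimator in this package assumes a specific statistical
structure; this module generates data with exactly that structure so the
whole pipeline can be exercised and validated without wet-lab input:

* cosine-shaped expression time courses sampled every 2 h over 24 h in two
  independent experiments (optionally extended with 48/72 h endpoint
  samples), with condition-specific amplitude scaling and phase shifts plus
  additive Gaussian noise;
* Cq tables that, together with the chosen amplification efficiencies,
  invert exactly to a planted relative-expression table under
  reference-gene normalization;
* exponential-window growth curves with a linear OD600-to-CFU/mL
  relationship under multiplicative lognormal noise.

Phase perturbations are specified in hours, positive meaning the perturbed
condition peaks EARLIER (a phase advance).  All randomness flows through a
``numpy.random.default_rng`` stream seeded from the design, so identical
inputs give byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cosinor import TWO_PI
from .errors import ConfigurationError, ValidationError
from .qpcr import DEFAULT_REFERENCE_GENES

__all__ = [
    "SyntheticDesign",
    "GeneTruth",
    "simulate_expression",
    "simulate_cq",
    "simulate_growth",
]

#: 2-h sampling over one 24-h cycle
DEFAULT_TIMEPOINTS = tuple(float(t) for t in range(2, 25, 2))


@dataclass
class SyntheticDesign:
    """Sampling design of a simulated co-culture time-course experiment.

    The defaults mirror a two-experiment design sampled every 2 h for 24 h
    with a presumed 24-h period; the first condition is the control.
    """

    genes: tuple[str, ...]
    conditions: tuple[str, ...]
    timepoints: tuple[float, ...] = DEFAULT_TIMEPOINTS
    replicates_per_timepoint: int = 2
    period: float = 24.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.genes = tuple(self.genes)
        self.conditions = tuple(self.conditions)
        self.timepoints = tuple(float(t) for t in self.timepoints)
        if len(set(self.genes)) != len(self.genes) or not self.genes:
            raise ValidationError("gene labels must be unique and non-empty")
        if not self.conditions:
            raise ValidationError("at least one condition is required")
        tp = np.asarray(self.timepoints)
        if tp.size == 0 or np.any(tp < 0) or np.any(np.diff(tp) <= 0):
            raise ValidationError("timepoints must be strictly increasing and >= 0")
        if self.replicates_per_timepoint < 1:
            raise ValidationError("replicates_per_timepoint must be >= 1")
        if self.period <= 0:
            raise ValidationError("period must be positive")

    @property
    def control(self) -> str:
        return self.conditions[0]

    @property
    def experiments(self) -> tuple[str, ...]:
        return tuple(f"exp{i + 1}" for i in range(self.replicates_per_timepoint))


@dataclass
class GeneTruth:
    """Ground-truth rhythm parameters for one simulated gene.

    ``mesor``, ``amplitude`` and ``acrophase`` (radians in (-2*pi, 0])
    define the control waveform; ``amplitude_scale`` and ``phase_shift``
    (hours, positive = advance) perturb it per condition; ``noise_sd`` is
    the Gaussian noise on the relative-expression scale.  An optional
    additive per-experiment offset models a batch effect (zero by default:
    the two experiments are treated as i.i.d. replicates).
    """

    mesor: float
    amplitude: float
    acrophase: float
    amplitude_scale: Mapping[str, float] = field(default_factory=dict)
    phase_shift: Mapping[str, float] = field(default_factory=dict)
    noise_sd: float = 0.0
    experiment_offset: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValidationError("amplitude must be >= 0")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if not (-TWO_PI < self.acrophase <= 0.0):
            raise ValidationError("acrophase must lie in (-2*pi, 0]")
        if any(s < 0 for s in self.amplitude_scale.values()):
            raise ValidationError("amplitude_scale must be >= 0")

    def waveform(self, times: np.ndarray, condition: str, period: float) -> np.ndarray:
        """Noise-free expression curve for one condition."""
        scale = self.amplitude_scale.get(condition, 1.0)
        shift = self.phase_shift.get(condition, 0.0)
        t = np.asarray(times, dtype=float)
        return self.mesor + self.amplitude * scale * np.cos(
            TWO_PI * (t + shift) / period + self.acrophase)


def _check_truths(design: SyntheticDesign,
                  truths: Mapping[str, GeneTruth]) -> None:
    missing = [g for g in design.genes if g not in truths]
    if missing:
        raise ConfigurationError(f"no simulation truth for genes: {missing}")


def simulate_expression(design: SyntheticDesign,
                        truths: Mapping[str, GeneTruth]) -> pd.DataFrame:
    """Simulate a long-format relative-expression table.

    For gene g, condition c, time t the value is

        mesor + amplitude * scale(c) * cos(2*pi*(t + shift(c))/period
                                           + acrophase) + eps,

    with ``eps ~ Normal(0, noise_sd**2)`` drawn independently per
    observation.  Returns a DataFrame with columns
    ``gene, condition, experiment, time_h, value``.
    """
    _check_truths(design, truths)
    rng = np.random.default_rng(design.seed)
    times = np.asarray(design.timepoints)
    records = []
    for gene in design.genes:
        truth = truths[gene]
        for condition in design.conditions:
            clean = truth.waveform(times, condition, design.period)
            for experiment in design.experiments:
                noise = rng.normal(0.0, truth.noise_sd, size=times.size) \
                    if truth.noise_sd > 0 else np.zeros(times.size)
                offset = truth.experiment_offset.get(experiment, 0.0)
                for t, v in zip(times, clean + offset + noise):
                    records.append((gene, condition, experiment, t, float(v)))
    return pd.DataFrame(records,
                        columns=["gene", "condition", "experiment", "time_h", "value"])


def simulate_cq(design: SyntheticDesign, truths: Mapping[str, GeneTruth],
                efficiencies: Mapping[str, float],
                reference_genes: Sequence[str] = DEFAULT_REFERENCE_GENES,
                reference_cq: float = 18.0,
                cq_noise_sd: float = 0.0) -> pd.DataFrame:
    """Simulate a Cq table that normalizes back to planted expression.

    Target-gene expression is drawn with :func:`simulate_expression` (the
    planted relative-expression table), reference genes are given a flat Cq
    of ``reference_cq``, and each target Cq is chosen so that
    efficiency-corrected normalization recovers the planted value exactly:

        Cq(g, s) = -log(value(g, s) * N(s)) / log(E_g),

    where N(s) is the geometric mean of the reference quantities for
    sample s.  ``cq_noise_sd`` adds Gaussian measurement noise on the Cq
    scale on top of the planted structure.  Planted expression must be
    positive (keep mesor comfortably above amplitude + noise).

    Returns a DataFrame ``gene, condition, experiment, time_h, cq``
    covering targets and references.
    """
    bad = {g: e for g, e in efficiencies.items() if e <= 1.0}
    if bad:
        raise ValidationError(f"amplification efficiency must exceed 1: {bad}")
    unknown_refs = [r for r in reference_genes if r not in design.genes]
    if unknown_refs:
        raise ConfigurationError(
            f"reference genes must be part of the design: {unknown_refs}")
    targets = [g for g in design.genes if g not in set(reference_genes)]
    target_design = SyntheticDesign(
        genes=tuple(targets), conditions=design.conditions,
        timepoints=design.timepoints,
        replicates_per_timepoint=design.replicates_per_timepoint,
        period=design.period, seed=design.seed)
    expr = simulate_expression(target_design, truths)
    if (expr["value"] <= 0).any():
        raise ConfigurationError(
            "planted expression must be positive to encode as Cq; "
            "raise the mesor or lower amplitude/noise")

    # per-sample normalization factor from the flat reference Cq values
    log_q_refs = [-reference_cq * math.log(efficiencies[r]) for r in reference_genes]
    log_norm = float(np.mean(log_q_refs))

    rng = np.random.default_rng(np.random.SeedSequence((design.seed, 7)))
    records = []
    for _, row in expr.iterrows():
        log_e = math.log(efficiencies[row["gene"]])
        cq = -(math.log(row["value"]) + log_norm) / log_e
        records.append((row["gene"], row["condition"], row["experiment"],
                        row["time_h"], cq))
    for ref in reference_genes:
        for condition in design.conditions:
            for experiment in design.experiments:
                for t in design.timepoints:
                    records.append((ref, condition, experiment, t, reference_cq))
    df = pd.DataFrame(records,
                      columns=["gene", "condition", "experiment", "time_h", "cq"])
    if cq_noise_sd > 0:
        df["cq"] = df["cq"] + rng.normal(0.0, cq_noise_sd, size=len(df))
    return df


def simulate_growth(slope: float, intercept: float = 0.0,
                    od_range: tuple[float, float] = (0.05, 1.0),
                    n_points: int = 8, noise_cv: float = 0.0,
                    seed: int | None = None,
                    time_window: tuple[float, float] = (2.0, 5.0)) -> pd.DataFrame:
    """Simulate an exponential-window growth curve.

    OD600 values span ``od_range`` over ``time_window`` hours and viable
    counts follow ``CFU/mL = slope * OD + intercept`` multiplied by
    lognormal noise with coefficient of variation ``noise_cv`` (mean 1, so
    the calibration stays unbiased on the original scale).

    Returns a DataFrame ``time_h, od600, cfu_per_ml``.
    """
    if slope <= 0:
        raise ValidationError("slope must be positive")
    lo, hi = od_range
    if not (0.0 < lo < hi <= 2.0):
        raise ValidationError("od_range must lie within (0, 2] with lo < hi")
    if noise_cv < 0:
        raise ValidationError("noise_cv must be >= 0")
    if n_points < 2:
        raise ValidationError("n_points must be >= 2")
    rng = np.random.default_rng(seed)
    times = np.linspace(time_window[0], time_window[1], n_points)
    od = np.linspace(lo, hi, n_points)
    cfu = slope * od + intercept
    if noise_cv > 0:
        sigma = math.sqrt(math.log(1.0 + noise_cv ** 2))
        cfu = cfu * rng.lognormal(-0.5 * sigma ** 2, sigma, size=n_points)
    return pd.DataFrame({"time_h": times, "od600": od, "cfu_per_ml": cfu})
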